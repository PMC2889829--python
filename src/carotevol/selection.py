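"""Pairwise positive-selection screen.

Implements the classic Nei–Gojobori (1986) counting method for synonymous
and nonsynonymous sites and differences, with the Jukes–Cantor multiple-hit
correction, followed by the screening procedure used for carotenoid
biosynthetic gene clusters: filter pairs by d_s < 1.5 (mutational
saturation) and d_n > 0.01 (informative substitutions), bin the surviving
d_n/d_s ratios to one decimal place, call the distribution bimodal when a
clearly separated upper mode sits at or above 1, flag the sequences
responsible for the upper mode, and compare elevated against non-elevated
comparisons with a Mann–Whitney U test under the normal approximation.

Site counting excludes single-nucleotide changes that would create a stop
codon and renormalizes over the remaining changes at that codon position;
difference counting averages over all mutational pathways between two
codons that avoid stop-codon intermediates. Codon pairs containing a gap,
an ambiguous base or a stop codon are skipped pairwise, as are the (rare)
pairs connected only through stop-codon pathways.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from scipy.stats import norm, rankdata

from .alignment import CodonAlignment
from .codons import genetic_code, single_neighbors

OK = "OK"
NC = "NC"
FILTERED = "FILTERED"

_AMBIGUOUS = set("N-")


class SelectionError(ValueError):
    pass


class InsufficientDataError(SelectionError):
    pass


# ---------------------------------------------------------------------------
# Nei–Gojobori site and difference counting
# ---------------------------------------------------------------------------


@dataclass
class CodonPairCounts:
    """NG86 sites and differences accumulated over one sequence pair.

    ``S`` and ``N`` are synonymous and nonsynonymous site counts (averaged
    over the two sequences), ``Sd``/``Nd`` the pathway-averaged difference
    counts; ``S + N`` equals three times the number of usable codons.
    """

    S: float = 0.0
    N: float = 0.0
    Sd: float = 0.0
    Nd: float = 0.0
    usable_codons: int = 0

    @property
    def pS(self) -> Optional[float]:
        return self.Sd / self.S if self.S > 0 else None

    @property
    def pN(self) -> Optional[float]:
        return self.Nd / self.N if self.N > 0 else None


@lru_cache(maxsize=None)
def codon_site_counts(codon: str, table_id: int = 1) -> Tuple[float, float]:
    """Synonymous/nonsynonymous site counts for one sense codon.

    Each codon position contributes the fraction of its single-nucleotide
    changes that are synonymous, among changes not creating a stop codon
    (renormalized over the remaining changes); the nonsynonymous count is
    the complement, so the two always sum to 3.
    """
    code = genetic_code(table_id)
    aa = code.get(codon)
    if aa is None or aa == "*":
        raise SelectionError(f"not a sense codon: {codon!r}")
    s_sites = 0.0
    for pos in range(3):
        syn = 0
        non_stop = 0
        for _, mutant in single_neighbors(codon):
            if mutant[:pos] + mutant[pos + 1 :] != codon[:pos] + codon[pos + 1 :]:
                continue  # not a change at this position
            target_aa = code[mutant]
            if target_aa == "*":
                continue
            non_stop += 1
            if target_aa == aa:
                syn += 1
        if non_stop:
            s_sites += syn / non_stop
    return s_sites, 3.0 - s_sites


@lru_cache(maxsize=None)
def codon_pair_differences(
    codon_a: str, codon_b: str, table_id: int = 1
) -> Optional[Tuple[float, float]]:
    """Pathway-averaged (Sd, Nd) between two sense codons.

    Averages synonymous/nonsynonymous step counts over every ordering of
    the differing positions whose intermediate codons are all sense codons.
    Returns ``None`` when the codons are connected only through stop-codon
    pathways (the pair is then skipped entirely).
    """
    code = genetic_code(table_id)
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return 0.0, 0.0
    syn_total = 0.0
    nonsyn_total = 0.0
    n_paths = 0
    for order in permutations(diff_positions):
        current = codon_a
        syn = nonsyn = 0
        valid = True
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if code[nxt] == "*":
                valid = False
                break
            if code[nxt] == code[current]:
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        if valid:
            syn_total += syn
            nonsyn_total += nonsyn
            n_paths += 1
    if n_paths == 0:
        return None
    return syn_total / n_paths, nonsyn_total / n_paths


def _usable(codon: str, code: Dict[str, str]) -> bool:
    return not (set(codon) & _AMBIGUOUS) and code.get(codon, "*") != "*"


def pairwise_ng86(seq_a: str, seq_b: str, table_id: int = 1) -> CodonPairCounts:
    """NG86 counts for one pair of equal-length, in-frame sequences."""
    if len(seq_a) != len(seq_b):
        raise SelectionError("sequences differ in length")
    if len(seq_a) % 3:
        raise SelectionError("sequence length is not a multiple of 3")
    code = genetic_code(table_id)
    counts = CodonPairCounts()
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        if not (_usable(ca, code) and _usable(cb, code)):
            continue
        diffs = codon_pair_differences(ca, cb, table_id)
        if diffs is None:
            continue
        sa, na = codon_site_counts(ca, table_id)
        sb, nb = codon_site_counts(cb, table_id)
        counts.S += (sa + sb) / 2.0
        counts.N += (na + nb) / 2.0
        counts.Sd += diffs[0]
        counts.Nd += diffs[1]
        counts.usable_codons += 1
    return counts


def jc_correct(p: float) -> Optional[float]:
    """Jukes–Cantor distance ``d = -(3/4) ln(1 - 4p/3)``; None when p >= 3/4."""
    if p < 0:
        raise SelectionError("proportion of differences must be non-negative")
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


# ---------------------------------------------------------------------------
# Pairwise rate table
# ---------------------------------------------------------------------------


@dataclass
class PairRates:
    id_a: str
    id_b: str
    dn: Optional[float]
    ds: Optional[float]
    ratio: Optional[float]
    status: str


@dataclass
class PairwiseRateTable:
    """Per-pair corrected d_n, d_s and their ratio, with a status flag.

    ``OK`` pairs carry a ratio; ``NC`` marks pairs whose Jukes–Cantor
    correction was undefined (p >= 3/4), whose d_s was zero, or which had
    no usable codons; ``FILTERED`` marks pairs rejected by the screening
    bounds.
    """

    pairs: List[PairRates] = field(default_factory=list)
    ids: Tuple[str, ...] = ()

    def __iter__(self):
        return iter(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def ok_pairs(self) -> List[PairRates]:
        return [p for p in self.pairs if p.status == OK]

    def ratios(self) -> List[float]:
        return [p.ratio for p in self.ok_pairs()]

    def to_rows(self) -> List[dict]:
        def fmt(x):
            return "NC" if x is None else x

        return [
            {
                "id_a": p.id_a,
                "id_b": p.id_b,
                "dn": fmt(p.dn),
                "ds": fmt(p.ds),
                "ratio": fmt(p.ratio) if p.status != FILTERED else p.ratio,
                "status": p.status,
            }
            for p in self.pairs
        ]

    def write_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.to_rows()).to_csv(path, sep="\t", index=False)


def build_rate_table(alignment: CodonAlignment, table_id: int = 1) -> PairwiseRateTable:
    """NG86 + Jukes–Cantor rates for every unordered sequence pair."""
    table = PairwiseRateTable(ids=alignment.ids)
    n = alignment.n_sequences
    for i in range(n):
        for j in range(i + 1, n):
            counts = pairwise_ng86(
                alignment.sequences[i], alignment.sequences[j], table_id
            )
            if counts.usable_codons == 0:
                table.pairs.append(
                    PairRates(alignment.ids[i], alignment.ids[j], None, None, None, NC)
                )
                continue
            dn = jc_correct(counts.pN)
            ds = jc_correct(counts.pS)
            if dn is None or ds is None or ds == 0.0:
                table.pairs.append(
                    PairRates(alignment.ids[i], alignment.ids[j], dn, ds, None, NC)
                )
            else:
                table.pairs.append(
                    PairRates(alignment.ids[i], alignment.ids[j], dn, ds, dn / ds, OK)
                )
    return table


def filter_pairs(
    table: PairwiseRateTable, dn_min: float = 0.01, ds_max: float = 1.5
) -> PairwiseRateTable:
    """Apply the saturation/informativeness bounds: keep d_s < ds_max, d_n > dn_min."""
    out = PairwiseRateTable(ids=table.ids)
    for p in table.pairs:
        if p.status == OK and not (p.ds < ds_max and p.dn > dn_min):
            out.pairs.append(PairRates(p.id_a, p.id_b, p.dn, p.ds, p.ratio, FILTERED))
        else:
            out.pairs.append(PairRates(p.id_a, p.id_b, p.dn, p.ds, p.ratio, p.status))
    return out


# ---------------------------------------------------------------------------
# Binning and bimodality
# ---------------------------------------------------------------------------


def round_half_away(value: float, decimals: int = 1) -> float:
    scale = 10**decimals
    return math.floor(abs(value) * scale + 0.5) / scale * (1 if value >= 0 else -1)


def bin_histogram(ratios: Sequence[float]) -> Dict[float, int]:
    """Counts of ratios rounded (half away from zero) to one decimal place."""
    hist: Dict[float, int] = {}
    for r in ratios:
        b = round_half_away(r, 1)
        hist[b] = hist.get(b, 0) + 1
    return dict(sorted(hist.items()))


def histogram_percentages(hist: Dict[float, int]) -> Dict[float, float]:
    total = sum(hist.values())
    if total == 0:
        return {}
    return {b: 100.0 * c / total for b, c in hist.items()}


def _dense_bins(hist: Dict[float, int]) -> Tuple[List[float], List[int]]:
    """Histogram over the full occupied bin range, empty bins included."""
    if not hist:
        return [], []
    lo = round(min(hist) * 10)
    hi = round(max(hist) * 10)
    centers = [b / 10 for b in range(lo, hi + 1)]
    counts = [hist.get(round(b * 10) / 10, 0) for b in centers]
    return centers, counts


def is_bimodal(
    hist: Dict[float, int],
    valley_ratio: float = 0.5,
    min_mode_fraction: float = 0.1,
) -> Tuple[bool, Optional[float], Optional[float]]:
    """Bimodality call on a one-decimal histogram.

    The distribution is called bimodal when the bins split into two
    clusters separated by a valley at least two bins (0.2 in ratio) wide,
    every valley bin strictly lower than both cluster peaks and below
    ``valley_ratio`` times the smaller peak, each cluster holding at least
    ``max(2, ceil(min_mode_fraction * n))`` comparisons, and the upper
    cluster's modal bin centered at >= 1.0. The mass and width conditions
    keep one- or two-comparison tail outliers, which are common in
    histograms of a few dozen pairwise ratios, from reading as modes.

    Returns ``(bimodal, lower mode center, upper mode center)``.
    """
    centers, counts = _dense_bins(hist)
    n = sum(counts)
    if n == 0:
        return False, None, None
    min_mass = max(2, math.ceil(min_mode_fraction * n))
    for i in range(len(counts)):
        for j in range(i + 1, len(counts)):  # valley window [i..j], width >= 2
            left, right = counts[:i], counts[j + 1 :]
            if sum(left) < min_mass or sum(right) < min_mass:
                continue
            left_peak, right_peak = max(left), max(right)
            threshold = valley_ratio * min(left_peak, right_peak)
            window = counts[i : j + 1]
            if any(w >= min(left_peak, right_peak) or w >= threshold for w in window):
                continue
            upper_center = max(
                c for c, cnt in zip(centers[j + 1 :], right) if cnt == right_peak
            )
            if upper_center < 1.0 - 1e-9:
                continue
            lower_center = min(
                c for c, cnt in zip(centers[:i], left) if cnt == left_peak
            )
            return True, lower_center, upper_center
    return False, None, None


# ---------------------------------------------------------------------------
# Mann–Whitney U (normal approximation, no tie/continuity correction)
# ---------------------------------------------------------------------------


def mann_whitney(
    group_a: Sequence[float], group_b: Sequence[float]
) -> Tuple[float, float, float]:
    """U statistic for ``group_b``, its normal-approximation Z, and two-tailed P.

    ``U`` counts (with half-weight for ties) how often a ``group_b`` value
    exceeds a ``group_a`` value, so under complete separation with
    ``group_b`` ranked lower, ``U = 0`` and ``Z`` is negative.
    """
    n1, n2 = len(group_a), len(group_b)
    if n1 == 0 or n2 == 0:
        raise SelectionError("both groups must be non-empty")
    combined = list(group_a) + list(group_b)
    ranks = rankdata(combined)
    r_b = float(sum(ranks[n1:]))
    u = r_b - n2 * (n2 + 1) / 2.0
    mean = n1 * n2 / 2.0
    sd = math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    z = (u - mean) / sd
    p = 2.0 * norm.sf(abs(z))
    return u, z, p


# ---------------------------------------------------------------------------
# Elevated-sequence detection and report
# ---------------------------------------------------------------------------


@dataclass
class SelectionReport:
    """Outcome of the screen on one filtered rate table."""

    histogram: Dict[float, int]
    bimodal: bool
    lower_mode: Optional[float]
    upper_mode: Optional[float]
    flagged_sequences: frozenset
    elevated: List[float]
    non_elevated: List[float]
    excluded: List[float]
    U: Optional[float] = None
    Z: Optional[float] = None
    two_tailed_P: Optional[float] = None
    elevated_mean: Optional[float] = None
    elevated_sd: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "histogram": {f"{b:.1f}": c for b, c in self.histogram.items()},
            "bimodal": self.bimodal,
            "lower_mode": self.lower_mode,
            "upper_mode": self.upper_mode,
            "flagged_sequences": sorted(self.flagged_sequences),
            "n_elevated": len(self.elevated),
            "n_non_elevated": len(self.non_elevated),
            "n_excluded": len(self.excluded),
            "U": self.U,
            "Z": self.Z,
            "two_tailed_P": self.two_tailed_P,
            "elevated_mean": self.elevated_mean,
            "elevated_sd": self.elevated_sd,
        }


def detect_elevated(
    table: PairwiseRateTable,
    tau: float = 0.9,
    valley_ratio: float = 0.5,
    min_mode_fraction: float = 0.1,
) -> SelectionReport:
    """Bimodality detection and elevated-sequence flagging on a filtered table.

    When the one-decimal histogram of OK ratios is bimodal with its upper
    mode at >= 1.0, a sequence is flagged as responsible when at least half
    of its OK comparisons have a ratio >= ``tau``. Elevated comparisons are
    flagged-vs-unflagged pairs; flagged-vs-flagged pairs are excluded from
    both groups (their ratios are aberrantly low); everything else forms the
    non-elevated group, and the two groups are compared by Mann–Whitney U.
    """
    if len(table.ids) < 2:
        raise InsufficientDataError("need at least two sequences")
    ratios = table.ratios()
    hist = bin_histogram(ratios)
    bimodal, lower_mode, upper_mode = is_bimodal(hist, valley_ratio, min_mode_fraction)

    flagged: set = set()
    if bimodal:
        per_seq: Dict[str, List[float]] = {}
        for p in table.ok_pairs():
            per_seq.setdefault(p.id_a, []).append(p.ratio)
            per_seq.setdefault(p.id_b, []).append(p.ratio)
        for sid, values in per_seq.items():
            if sum(1 for v in values if v >= tau) >= len(values) / 2.0:
                flagged.add(sid)

    elevated, non_elevated, excluded = [], [], []
    for p in table.ok_pairs():
        a_fl, b_fl = p.id_a in flagged, p.id_b in flagged
        if a_fl and b_fl:
            excluded.append(p.ratio)
        elif a_fl or b_fl:
            elevated.append(p.ratio)
        else:
            non_elevated.append(p.ratio)

    report = SelectionReport(
        histogram=hist,
        bimodal=bimodal,
        lower_mode=lower_mode,
        upper_mode=upper_mode,
        flagged_sequences=frozenset(flagged),
        elevated=elevated,
        non_elevated=non_elevated,
        excluded=excluded,
    )
    if elevated:
        mean = sum(elevated) / len(elevated)
        report.elevated_mean = mean
        if len(elevated) > 1:
            var = sum((v - mean) ** 2 for v in elevated) / (len(elevated) - 1)
            report.elevated_sd = math.sqrt(var)
        else:
            report.elevated_sd = 0.0
    if elevated and non_elevated:
        report.U, report.Z, report.two_tailed_P = mann_whitney(elevated, non_elevated)
    return report


def run_selection_screen(
    alignment: CodonAlignment,
    dn_min: float = 0.01,
    ds_max: float = 1.5,
    tau: float = 0.9,
    table_id: int = 1,
    valley_ratio: float = 0.5,
) -> Tuple[PairwiseRateTable, SelectionReport]:
    """Full screen: rate table, filters, bimodality and flagging."""
    table = filter_pairs(build_rate_table(alignment, table_id), dn_min, ds_max)
    return table, detect_elevated(table, tau=tau, valley_ratio=valley_ratio)
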