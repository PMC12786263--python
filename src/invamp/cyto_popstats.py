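"""Cytogenetic and population statistics.

Cytotype frequency estimates with binomial sampling error, a
Hardy-Weinberg chi-square test on three genotype classes (df = 1, one
estimated allele frequency, no continuity correction), 2x2 contingency
chi-square, crossover-focus (MLH1) recombination maps along the
synaptonemal complex, and a Mann-Whitney U test with exact enumeration at
small sample sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps


def round_half_away(x: float, ndigits: int) -> float:
    """Round half away from zero (reporting convention for tables)."""
    q = 10 ** ndigits
    return math.copysign(math.floor(abs(x) * q + 0.5) / q, x)


# ---------------------------------------------------------------------------
# genotype counts and frequencies
# ---------------------------------------------------------------------------

@dataclass
class GenotypeCounts:
    """Counts of M/M, S/M and S/S individuals (e.g. one sex or pooled)."""

    n_MM: int
    n_SM: int
    n_SS: int
    group: str = "pooled"

    def __post_init__(self):
        if min(self.n_MM, self.n_SM, self.n_SS) < 0:
            raise ValueError("genotype counts must be nonnegative")
        if self.N < 1:
            raise ValueError("at least one individual required")

    @property
    def N(self) -> int:
        return self.n_MM + self.n_SM + self.n_SS

    @property
    def allele_M_count(self) -> int:
        return 2 * self.n_MM + self.n_SM

    def swapped(self) -> "GenotypeCounts":
        """Relabel M <-> S (used by symmetry checks)."""
        return GenotypeCounts(self.n_SS, self.n_SM, self.n_MM, self.group)


@dataclass
class FrequencyEstimate:
    p: float
    se: float
    denominator: int            # individuals or chromosomes

    def rounded(self, ndigits: int = 2) -> tuple[float, float]:
        return round_half_away(self.p, ndigits), round_half_away(self.se, ndigits)


def cytotype_frequencies(
    counts: GenotypeCounts, ddof: int = 1
) -> tuple[FrequencyEstimate, FrequencyEstimate]:
    """(heterozygote frequency, rearranged-allele frequency) with SEs.

    The heterozygote frequency is counted over N individuals, the allele
    frequency over 2N chromosomes.  The sampling error is
    sqrt(p (1 - p) / (N - ddof)); the default ddof=1 uses the unbiased
    sample-variance denominator, ddof=0 gives the plain binomial form.
    """
    N = counts.N

    def est(x: int, denom: int) -> FrequencyEstimate:
        p = x / denom
        d = denom - ddof
        se = math.sqrt(p * (1 - p) / d) if d > 0 else 0.0
        return FrequencyEstimate(p=p, se=se, denominator=denom)

    return est(counts.n_SM, N), est(counts.allele_M_count, 2 * N)


# ---------------------------------------------------------------------------
# chi-square tests
# ---------------------------------------------------------------------------

@dataclass
class HWEResult:
    chi2: float
    p_value: float
    df: int = 1
    expected: tuple[float, float, float] = field(default=(0.0, 0.0, 0.0))


def hwe_test(counts: GenotypeCounts) -> HWEResult:
    """Pearson chi-square against Hardy-Weinberg proportions.

    Expected counts are N * (p^2, 2pq, q^2) at the estimated allele
    frequency; df = 1 (three classes, one estimated parameter); no
    continuity correction.  A monomorphic sample returns chi2 = 0, p = 1
    by convention.
    """
    N = counts.N
    p = counts.allele_M_count / (2 * N)
    q = 1.0 - p
    if p in (0.0, 1.0):
        return HWEResult(chi2=0.0, p_value=1.0,
                         expected=(N * p * p, 2 * N * p * q, N * q * q))
    exp = (N * p * p, 2 * N * p * q, N * q * q)
    obs = (counts.n_MM, counts.n_SM, counts.n_SS)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(obs, exp))
    return HWEResult(chi2=chi2, p_value=float(sps.chi2.sf(chi2, 1)),
                     expected=exp)


def contingency_chisq(
    table: list[list[float]] | np.ndarray, correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table (optional Yates correction)."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin in contingency table")
    n = t.sum()
    exp = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
    diff = np.abs(t - exp)
    if correction:
        diff = np.maximum(diff - 0.5, 0.0)
    chi2 = float((diff ** 2 / exp).sum())
    return chi2, float(sps.chi2.sf(chi2, 1))


# ---------------------------------------------------------------------------
# recombination maps
# ---------------------------------------------------------------------------

@dataclass
class MLH1Spread:
    """One bivalent: SC length, centromere position and focus positions (um)."""

    sc_length: float
    centromere_pos: float
    foci: list[float]

    def validate(self, name: str = "spread") -> None:
        if not 0 <= self.centromere_pos <= self.sc_length:
            raise ValueError(f"{name}: centromere outside [0, SC length]")
        for f in self.foci:
            if not 0 <= f <= self.sc_length:
                raise ValueError(
                    f"{name}: MLH1 focus at {f} um outside [0, {self.sc_length}]"
                )


@dataclass
class RecombinationMap:
    bin_edges: np.ndarray
    proportions: np.ndarray
    by_focus_class: dict[int, np.ndarray]
    mean_sc_length: float
    mean_centromere: float
    n_foci: int


def mlh1_recombination_map(
    spreads: list[MLH1Spread],
    target_bin: float = 1.0,
    relative_to_centromere: bool = False,
) -> RecombinationMap:
    """Proportion of crossover foci per ~target_bin um interval of the SC.

    Focus positions are rescaled to the mean SC length, the axis is split
    into round(mean length / target_bin) equal bins, and per-bin focus
    proportions are reported overall and stratified by the number of foci
    on the bivalent (classes 1..5, >5 pooled into 5).  With
    ``relative_to_centromere`` the axis is centromere-centred instead of
    anchored at one SC end.
    """
    if not spreads:
        raise ValueError("no spreads supplied")
    for i, sp in enumerate(spreads):
        sp.validate(name=f"spread {i}")
    mean_len = float(np.mean([sp.sc_length for sp in spreads]))
    mean_cen = float(np.mean(
        [sp.centromere_pos * mean_len / sp.sc_length for sp in spreads]))
    n_bins = max(1, round(mean_len / target_bin))
    if relative_to_centromere:
        edges = np.linspace(-mean_cen, mean_len - mean_cen, n_bins + 1)
    else:
        edges = np.linspace(0.0, mean_len, n_bins + 1)

    def positions(sp: MLH1Spread) -> np.ndarray:
        x = np.asarray(sp.foci, dtype=float) * (mean_len / sp.sc_length)
        if relative_to_centromere:
            x = x - mean_cen
        return x

    counts = np.zeros(n_bins)
    by_class: dict[int, np.ndarray] = {}
    for sp in spreads:
        x = positions(sp)
        if x.size == 0:
            continue
        h, _ = np.histogram(x, bins=edges)
        # the top edge is inclusive so a telomeric focus is not dropped
        counts += h
        cls = min(len(sp.foci), 5)
        by_class.setdefault(cls, np.zeros(n_bins))
        by_class[cls] += h
    total = counts.sum()
    props = counts / total if total > 0 else counts
    by_class_props = {
        c: (v / v.sum() if v.sum() > 0 else v) for c, v in by_class.items()
    }
    return RecombinationMap(
        bin_edges=edges, proportions=props, by_focus_class=by_class_props,
        mean_sc_length=mean_len, mean_centromere=mean_cen,
        n_foci=int(total),
    )


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="stable")
    ranks = np.empty(values.size, dtype=float)
    sv = values[order]
    i = 0
    while i < sv.size:
        j = i
        while j + 1 < sv.size and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def mann_whitney_u(
    x, y, alternative: str = "two-sided", exact_limit: int = 12
) -> tuple[float, float]:
    """Rank-sum U for sample x against y with midrank ties.

    Exact enumeration over all C(n1+n2, n1) group assignments when
    n1 + n2 <= exact_limit (valid under ties); otherwise the normal
    approximation with the tie-corrected variance.  U is the statistic of
    x (large U means x tends larger).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be nonempty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    mu = n1 * n2 / 2.0

    if n1 + n2 <= exact_limit:
        n = n1 + n2
        us = []
        base = n1 * (n1 + 1) / 2.0
        for comb in combinations(range(n), n1):
            us.append(ranks[list(comb)].sum() - base)
        us = np.asarray(us)
        eps = 1e-9
        if alternative == "two-sided":
            p = float(np.mean(np.abs(us - mu) >= abs(u_obs - mu) - eps))
        elif alternative == "greater":
            p = float(np.mean(us >= u_obs - eps))
        else:
            p = float(np.mean(us <= u_obs + eps))
        return u_obs, min(p, 1.0)

    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1)))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return u_obs, 1.0
    sd = math.sqrt(var)
    # continuity correction keeps the approximation close to the exact
    # enumeration at small n
    if alternative == "two-sided":
        z = max(abs(u_obs - mu) - 0.5, 0.0) / sd
        p = 2 * float(sps.norm.sf(z))
    elif alternative == "greater":
        p = float(sps.norm.sf((u_obs - mu - 0.5) / sd))
    else:
        p = float(sps.norm.cdf((u_obs - mu + 0.5) / sd))
    return u_obs, min(p, 1.0)
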