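"""Reporter-count statistics and the multiplicative model of genetic synergy.

The central question these routines answer: do two transcription factors act
independently on a reporter, or synergistically?  Under the multiplicative
(epistasis) null, the fold-change effect of losing both factors equals the
product of the fold changes of losing each one.  Per-animal reporter-positive
neuron counts are first converted to fold changes against a reference genotype;
the expected triple-mutant fold change is the product of the two double-mutant
mean fold changes, with first-order error propagation

    sd_E = E * (s_a / m_a + s_b / m_b)

(relative errors add; a quadrature mode is available).  The observed triple
mutant is then tested against the fixed expectation with a one-sample t test on
its per-animal fold changes.  An observed mean significantly below the
expectation is a synergistic loss.

Also here: the pairwise two-tailed t procedure with an F-test variance pretest
and Bonferroni correction over all pairs, the one-tailed regional t procedure
with Benjamini-Hochberg control, Fisher's exact test for on/off rescue tables,
and the behavioral index formulas (response, chemotaxis, avoidance, dauer).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import bh_adjust


@dataclass
class ReporterCounts:
    """Per-animal reporter-positive neuron counts for one genotype."""

    genotype: str
    values: np.ndarray
    region: str | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 1:
            raise ValueError(f"{self.genotype}: at least one animal required")
        if np.any(self.values < 0):
            raise ValueError(f"{self.genotype}: counts must be non-negative")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def mean(self) -> float:
        return float(self.values.mean())


@dataclass(frozen=True)
class FoldChangeStat:
    genotype: str
    mean_fc: float
    sd_fc: float
    fold_changes: tuple

    @property
    def rel_err(self) -> float:
        if self.mean_fc == 0:
            return np.nan
        return self.sd_fc / self.mean_fc


@dataclass
class SynergyResult:
    expected_fc: float
    sd_expected: float
    observed_mean_fc: float
    observed_sd_fc: float
    t_statistic: float
    p_value: float
    verdict: str                  # synergistic_loss | consistent_with_multiplicative |
                                  # greater_than_expected | degenerate
    n: int


@dataclass(frozen=True)
class BehaviorIndex:
    assay: str
    value: float
    n: int


# ---------------------------------------------------------------------------
# t-test procedures
# ---------------------------------------------------------------------------

def _variance_pretest_ttest(a, b, alternative: str = "two-sided"):
    """Two-sample t with an F-test pretest choosing pooled vs Welch variance,
    mirroring the spreadsheet F.TEST / T.TEST idiom."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        equal_var = True
    else:
        f = va / vb if vb > 0 else np.inf
        dfa, dfb = a.size - 1, b.size - 1
        p_f = 2 * min(stats.f.cdf(f, dfa, dfb), stats.f.sf(f, dfa, dfb)) if np.isfinite(f) else 0.0
        equal_var = p_f >= 0.05
    res = stats.ttest_ind(a, b, equal_var=equal_var, alternative=alternative)
    return float(res.statistic), float(res.pvalue), equal_var


def pairwise_reporter_tests(groups) -> pd.DataFrame:
    """All pairwise two-tailed t tests with Bonferroni correction over pairs.

    Returns a DataFrame with one row per genotype pair: t statistic, raw p,
    Bonferroni-adjusted p (capped at 1) and whether pooled variance was used.
    """
    groups = list(groups)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if g.n < 2:
            raise ValueError(f"group {g.genotype!r} has fewer than 2 animals")
    rows = []
    pairs = list(itertools.combinations(groups, 2))
    for a, b in pairs:
        t, p, pooled = _variance_pretest_ttest(a.values, b.values)
        if np.isnan(p):  # identical constant groups
            t, p = 0.0, 1.0
        rows.append({"genotype_a": a.genotype, "genotype_b": b.genotype,
                     "t": t, "p_raw": p, "pooled_variance": pooled})
    df = pd.DataFrame(rows)
    df["p_adjusted"] = np.minimum(df["p_raw"] * len(pairs), 1.0)
    return df


def regional_reporter_tests(
    regions: dict[str, tuple[ReporterCounts, ReporterCounts]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-tailed (mutant < control) t tests per anatomical region, BH-adjusted
    over all regions in the experiment.

    ``regions`` maps region label -> (mutant, control) count groups.
    """
    rows = []
    for region, (mutant, control) in regions.items():
        t, p, pooled = _variance_pretest_ttest(mutant.values, control.values,
                                               alternative="less")
        if np.isnan(p):
            t, p = 0.0, 1.0
        rows.append({"region": region, "t": t, "p_raw": p, "pooled_variance": pooled})
    df = pd.DataFrame(rows)
    df["p_adjusted"] = bh_adjust(df["p_raw"].to_numpy())
    df["rejected"] = df["p_adjusted"] <= alpha
    return df


# ---------------------------------------------------------------------------
# multiplicative model
# ---------------------------------------------------------------------------

def fold_changes(groups, reference: str) -> dict[str, FoldChangeStat]:
    """Per-animal counts divided by the reference genotype's mean count."""
    groups = list(groups)
    by_name = {g.genotype: g for g in groups}
    if reference not in by_name:
        raise ValueError(f"reference genotype {reference!r} not among groups")
    ref_mean = by_name[reference].mean
    if ref_mean <= 0:
        raise ValueError("reference mean must be positive")
    out = {}
    for g in groups:
        fcs = g.values / ref_mean
        out[g.genotype] = FoldChangeStat(
            genotype=g.genotype,
            mean_fc=float(fcs.mean()),
            sd_fc=float(fcs.std(ddof=1)) if fcs.size > 1 else 0.0,
            fold_changes=tuple(float(x) for x in fcs),
        )
    return out


def expected_multiplicative(
    fc_a: FoldChangeStat,
    fc_b: FoldChangeStat,
    error_mode: str = "additive",
) -> tuple[float, float]:
    """Expected fold change of the combined mutant under the multiplicative
    null: ``E = m_a * m_b`` with propagated error
    ``sd_E = E * (s_a/m_a + s_b/m_b)`` (additive relative errors, the default)
    or ``sd_E = E * sqrt((s_a/m_a)^2 + (s_b/m_b)^2)`` (quadrature)."""
    if fc_a.mean_fc <= 0 or fc_b.mean_fc <= 0:
        raise ValueError("mean fold changes must be positive")
    E = fc_a.mean_fc * fc_b.mean_fc
    if error_mode == "additive":
        sd = E * (fc_a.rel_err + fc_b.rel_err)
    elif error_mode == "quadrature":
        sd = E * float(np.hypot(fc_a.rel_err, fc_b.rel_err))
    else:
        raise ValueError("error_mode must be 'additive' or 'quadrature'")
    return float(E), float(sd)


def synergy_test(
    triple: ReporterCounts,
    reference: ReporterCounts,
    expected_fc: float,
    sd_expected: float = 0.0,
    alternative: str = "two-sided",
    alpha: float = 0.05,
    conservative: bool = False,
) -> SynergyResult:
    """One-sample t test of the triple mutant's per-animal fold changes against
    the fixed multiplicative expectation.

    ``conservative=True`` widens the test by folding the propagated uncertainty
    of the expectation into the denominator: t = (mean - E) /
    sqrt(sem^2 + sd_expected^2), df = n - 1.  Verdict is ``synergistic_loss``
    when the observed mean is below E with p < alpha, ``greater_than_expected``
    above E with p < alpha, else ``consistent_with_multiplicative``;
    zero-variance groups whose mean differs from E are ``degenerate``.
    """
    if triple.n < 2:
        raise ValueError("triple-mutant group needs at least 2 animals")
    if reference.mean <= 0:
        raise ValueError("reference mean must be positive")
    fcs = triple.values / reference.mean
    mean, sd = float(fcs.mean()), float(fcs.std(ddof=1))
    n = fcs.size
    if sd == 0 and not (conservative and sd_expected > 0):
        if mean == expected_fc:
            t, p, verdict = 0.0, 1.0, "consistent_with_multiplicative"
        else:
            t, p, verdict = np.inf if mean > expected_fc else -np.inf, 0.0, "degenerate"
        return SynergyResult(expected_fc, sd_expected, mean, sd, t, p, verdict, n)

    if conservative:
        se = float(np.sqrt(sd**2 / n + sd_expected**2))
        t = (mean - expected_fc) / se
        if alternative == "two-sided":
            p = 2 * stats.t.sf(abs(t), n - 1)
        elif alternative == "less":
            p = stats.t.cdf(t, n - 1)
        else:
            p = stats.t.sf(t, n - 1)
    else:
        res = stats.ttest_1samp(fcs, expected_fc, alternative=alternative)
        t, p = float(res.statistic), float(res.pvalue)
    if p < alpha and mean < expected_fc:
        verdict = "synergistic_loss"
    elif p < alpha and mean > expected_fc:
        verdict = "greater_than_expected"
    else:
        verdict = "consistent_with_multiplicative"
    return SynergyResult(expected_fc, sd_expected, mean, sd, float(t), float(p), verdict, n)


# ---------------------------------------------------------------------------
# rescue and behavior
# ---------------------------------------------------------------------------

def rescue_test(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 on/off contingency table.

    Returns (odds ratio, p).  The odds ratio is 0 or inf for degenerate cells,
    as in the exact conditional formulation.
    """
    table = np.asarray(table)
    if table.shape != (2, 2) or np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        raise ValueError("table must be a 2x2 array of non-negative integers")
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def behavior_index(assay: str, **counts) -> BehaviorIndex:
    """Population behavioral indexes, one formula per assay.

    response:            RI = responses / strokes                         in [0, 1]
    chemotaxis_quadrant: CI = (test_quadrants - control_quadrants) / total   [-1, 1]
    chemotaxis_halves:   CI = (test_half - control_half) / total             [-1, 1]
    avoidance_sectors:   AI = (sectors_ab - sectors_ef) / total              [-1, 1]
    avoidance_drop:      AI = responses / drops                           in [0, 1]
    dauer_fraction:      dauers / scored                                  in [0, 1]
    """
    def req(*names):
        vals = []
        for name in names:
            if name not in counts:
                raise ValueError(f"{assay} requires {name!r}")
            vals.append(float(counts[name]))
        return vals

    if assay == "response":
        responses, strokes = req("responses", "strokes")
        if strokes <= 0:
            raise ValueError("strokes must be positive")
        return BehaviorIndex(assay, responses / strokes, int(strokes))
    if assay == "chemotaxis_quadrant":
        t, c, total = req("test_quadrants", "control_quadrants", "total")
    elif assay == "chemotaxis_halves":
        t, c, total = req("test_half", "control_half", "total")
    elif assay == "avoidance_sectors":
        t, c, total = req("sectors_ab", "sectors_ef", "total")
    elif assay == "avoidance_drop":
        responses, drops = req("responses", "drops")
        if drops <= 0:
            raise ValueError("drops must be positive")
        return BehaviorIndex(assay, responses / drops, int(drops))
    elif assay == "dauer_fraction":
        dauers, scored = req("dauers", "scored")
        if scored <= 0:
            raise ValueError("scored must be positive")
        return BehaviorIndex(assay, dauers / scored, int(scored))
    else:
        raise ValueError(f"unknown assay {assay!r}")
    if total <= 0:
        raise ValueError("total must be positive")
    return BehaviorIndex(assay, (t - c) / total, int(total))


def dauer_fold_induction(induced: BehaviorIndex, control: BehaviorIndex) -> float:
    """Fold induction of dauer entry: induced fraction / control fraction."""
    if induced.assay != "dauer_fraction" or control.assay != "dauer_fraction":
        raise ValueError("both indexes must be dauer fractions")
    if control.value <= 0:
        raise ValueError("control dauer fraction must be positive")
    return induced.value / control.value


def normality_check(values, alpha: float = 0.05) -> tuple[float, bool]:
    """Shapiro-Wilk normality pretest for final behavior indexes."""
    w, p = stats.shapiro(np.asarray(values, float))
    return float(p), bool(p >= alpha)


# ---------------------------------------------------------------------------
# long-format I/O
# ---------------------------------------------------------------------------

def read_reporter_tsv(path) -> list[ReporterCounts]:
    """Long-format TSV (genotype, region, animal_id, count) -> one group per
    (genotype, region) combination."""
    df = pd.read_csv(path, sep="\t")
    groups = []
    keys = ["genotype"] + (["region"] if "region" in df.columns else [])
    for key, sub in df.groupby(keys, sort=False):
        genotype = key[0] if isinstance(key, tuple) else key
        region = key[1] if isinstance(key, tuple) and len(key) > 1 else None
        groups.append(ReporterCounts(genotype=genotype,
                                     values=sub["count"].to_numpy(),
                                     region=region))
    return groups


def write_reporter_tsv(groups, path) -> None:
    with open(path, "w") as fh:
        fh.write("genotype\tregion\tanimal_id\tcount\n")
        for g in groups:
            for i, v in enumerate(g.values):
                fh.write(f"{g.genotype}\t{g.region or '.'}\t{i}\t{v:g}\n")
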