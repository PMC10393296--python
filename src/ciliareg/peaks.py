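"""ChIP-seq peak handling: narrowPeak I/O, peak-to-gene annotation under a
strand-aware TSS window, genomic-feature summaries, and TF prioritization with
outlier detection.

Annotation model
----------------
Each peak is reduced to a point anchor (the summit when the caller reported one,
else the interval midpoint).  The anchor is classified against the gene models
with a fixed precedence:

``promoter``    anchor within [TSS - upstream, TSS + downstream) in transcript
                orientation (default -2000/+1000);
``genic``       anchor inside a gene span;
``downstream``  anchor within 3 kb past a gene end in transcript orientation;
``intergenic``  everything else.

The assigned gene is the one whose TSS window contains the anchor (nearest TSS
among several), otherwise the gene with the nearest TSS; ties break to the
lexicographically smaller gene id.  Signed distances are in transcript
orientation, negative upstream of the TSS.

TF prioritization regresses the number of battery genes bound on the total peak
count across TFs (ordinary least squares) and flags TFs whose externally
studentized residual exceeds the two-sided t critical value at a
Bonferroni-adjusted 0.05 level — a TF binding the battery far in excess of what
its overall peak count predicts.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.outliers_influence import OLSInfluence

from .battery import CATEGORIES, GeneBattery

DOWNSTREAM_EXTENT = 3000  # bp past the gene end still called "downstream"
FEATURES = ("promoter", "genic", "downstream", "intergenic")


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    summit_offset: int = -1
    score: float = 0.0
    signal: float = 0.0
    name: str = "."

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid peak interval [{self.start}, {self.end})")
        if self.summit_offset != -1 and not (0 <= self.summit_offset < self.end - self.start):
            raise ValueError(f"summit offset {self.summit_offset} outside peak")

    @property
    def anchor(self) -> int:
        """Point position: summit if present, else midpoint."""
        if self.summit_offset >= 0:
            return self.start + self.summit_offset
        return self.start + (self.end - self.start) // 2


@dataclass
class PeakSet:
    tf_name: str
    peaks: list[Peak] = field(default_factory=list)
    dataset_id: str = ""

    def __post_init__(self):
        self.peaks = sorted(self.peaks, key=lambda p: (p.chrom, p.start, p.end))

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def chromosomes(self) -> set[str]:
        return {p.chrom for p in self.peaks}


@dataclass(frozen=True)
class PeakAnnotation:
    peak: Peak
    feature: str
    gene_id: str | None
    distance_to_tss: int | None


@dataclass(frozen=True)
class TFBindingSummary:
    tf_name: str
    total_peaks: int
    battery_genes_bound: int
    battery_fraction: float
    core_fraction: float
    subtype_fraction: float
    bound_gene_ids: frozenset = frozenset()


@dataclass
class OutlierReport:
    table: pd.DataFrame  # tf_name, total_peaks, battery_genes_bound, residual, flagged
    slope: float
    intercept: float
    critical_value: float

    def flagged_tfs(self) -> list[str]:
        return list(self.table.loc[self.table["flagged"], "tf_name"])


# ---------------------------------------------------------------------------
# narrowPeak I/O
# ---------------------------------------------------------------------------

def read_narrowpeak(path, tf_name: str = "", dataset_id: str = "") -> PeakSet:
    """Parse an ENCODE narrowPeak (BED6+4) file; BED3/BED6 are accepted as a
    fallback with missing fields defaulted.  Malformed lines raise ValueError."""
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) not in (3, 6, 10):
                raise ValueError(
                    f"{path}:{lineno}: expected 3, 6 or 10 columns, got {len(parts)}"
                )
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                name = parts[3] if len(parts) > 3 else "."
                score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
                signal = float(parts[6]) if len(parts) == 10 else 0.0
                summit = int(parts[9]) if len(parts) == 10 else -1
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field ({exc})") from None
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start")
            peaks.append(Peak(chrom, start, end, summit_offset=summit,
                              score=score, signal=signal, name=name))
    return PeakSet(tf_name=tf_name or str(path), peaks=peaks, dataset_id=dataset_id)


def write_narrowpeak(peakset: PeakSet, path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peakset):
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{peakset.tf_name}_{i}\t"
                f"{p.score:g}\t.\t{p.signal:g}\t-1\t-1\t{p.summit_offset}\n"
            )


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

class _ChromIndex:
    """Sorted per-chromosome gene-model arrays for window queries."""

    def __init__(self, models):
        order = np.argsort([m.tss for m in models], kind="stable")
        self.models = [models[i] for i in order]
        self.tss = [m.tss for m in self.models]
        span_order = sorted(range(len(models)), key=lambda i: self.models[i].start)
        self.span_models = [self.models[i] for i in span_order]
        self.span_starts = [m.start for m in self.span_models]
        self.max_span = max((m.end - m.start for m in models), default=0)

    def within(self, anchor: int, radius: int):
        lo = bisect.bisect_left(self.tss, anchor - radius)
        hi = bisect.bisect_right(self.tss, anchor + radius)
        return self.models[lo:hi]

    def nearest(self, anchor: int):
        """All models at the minimal |anchor - tss| distance."""
        pos = bisect.bisect_left(self.tss, anchor)
        best, best_d = [], None
        for i in (pos - 1, pos, pos + 1):
            if 0 <= i < len(self.tss):
                d = abs(self.tss[i] - anchor)
                if best_d is None or d < best_d:
                    best, best_d = [self.models[i]], d
                elif d == best_d:
                    best.append(self.models[i])
        # ties can extend beyond immediate neighbours when TSSs coincide
        if best_d is not None:
            lo = bisect.bisect_left(self.tss, anchor - best_d)
            hi = bisect.bisect_right(self.tss, anchor + best_d)
            best = [m for m in self.models[lo:hi] if abs(m.tss - anchor) == best_d]
        return best

    def covering(self, anchor: int):
        lo = bisect.bisect_right(self.span_starts, anchor - self.max_span)
        hi = bisect.bisect_right(self.span_starts, anchor)
        return [m for m in self.span_models[lo:hi] if m.start <= anchor < m.end]


def _signed_distance(anchor: int, model) -> int:
    return anchor - model.tss if model.strand == "+" else model.tss - anchor


def annotate_peaks(
    peaks: PeakSet,
    models,
    tss_window: tuple[int, int] = (2000, 1000),
) -> list[PeakAnnotation]:
    """Assign every peak one feature class and one gene (see module docstring)."""
    models = list(models)
    if not models:
        raise ValueError("empty gene-model set")
    up, down = tss_window
    by_chrom: dict[str, list] = {}
    for m in models:
        by_chrom.setdefault(m.chrom, []).append(m)
    index = {chrom: _ChromIndex(ms) for chrom, ms in by_chrom.items()}

    out = []
    for peak in peaks:
        idx = index.get(peak.chrom)
        if idx is None:
            out.append(PeakAnnotation(peak, "intergenic", None, None))
            continue
        anchor = peak.anchor

        promoter_hits = []
        for m in idx.within(anchor, max(up, down)):
            d = _signed_distance(anchor, m)
            if -up <= d < down:
                promoter_hits.append((abs(d), m.gene_id, m, d))
        if promoter_hits:
            promoter_hits.sort(key=lambda t: (t[0], t[1]))
            _, _, m, d = promoter_hits[0]
            out.append(PeakAnnotation(peak, "promoter", m.gene_id, d))
            continue

        covering = idx.covering(anchor)
        if covering:
            m = min(covering, key=lambda m: (abs(_signed_distance(anchor, m)), m.gene_id))
            out.append(PeakAnnotation(peak, "genic", m.gene_id, _signed_distance(anchor, m)))
            continue

        downstream_hits = []
        for m in idx.within(anchor, idx.max_span + DOWNSTREAM_EXTENT):
            if m.strand == "+" and m.end <= anchor < m.end + DOWNSTREAM_EXTENT:
                downstream_hits.append(m)
            elif m.strand == "-" and m.start - DOWNSTREAM_EXTENT <= anchor < m.start:
                downstream_hits.append(m)
        if downstream_hits:
            m = min(downstream_hits,
                    key=lambda m: (abs(_signed_distance(anchor, m)), m.gene_id))
            out.append(
                PeakAnnotation(peak, "downstream", m.gene_id, _signed_distance(anchor, m))
            )
            continue

        nearest = idx.nearest(anchor)
        m = min(nearest, key=lambda m: m.gene_id)
        out.append(PeakAnnotation(peak, "intergenic", m.gene_id, _signed_distance(anchor, m)))
    return out


def feature_distribution(annotations) -> dict[str, float]:
    """Fraction of peaks per feature class; fractions sum to 1."""
    annotations = list(annotations)
    if not annotations:
        raise ValueError("no annotations")
    counts = {f: 0 for f in FEATURES}
    for a in annotations:
        counts[a.feature] += 1
    n = len(annotations)
    return {f: c / n for f, c in counts.items()}


def battery_binding(
    annotations,
    battery: GeneBattery,
    tf_name: str = "",
    total_peaks: int | None = None,
    features: tuple[str, ...] = ("promoter",),
) -> TFBindingSummary:
    """Summarize how many battery genes carry at least one peak.

    A battery gene counts as bound when >= 1 peak is assigned to it with a
    feature class in ``features`` (default: promoter assignments, i.e. binding
    within the regulatory TSS window; pass ``features=FEATURES`` to count any
    assignment).
    """
    annotations = list(annotations)
    battery_ids = battery.gene_ids()
    bound = {
        a.gene_id
        for a in annotations
        if a.gene_id in battery_ids and a.feature in features
    }
    n_total = len(battery)

    def frac(category: str) -> float:
        ids = battery.by_category(category)
        return len(bound & ids) / len(ids) if ids else 0.0

    return TFBindingSummary(
        tf_name=tf_name,
        total_peaks=total_peaks if total_peaks is not None else len(annotations),
        battery_genes_bound=len(bound),
        battery_fraction=len(bound) / n_total if n_total else 0.0,
        core_fraction=frac("core"),
        subtype_fraction=frac("subtype"),
        bound_gene_ids=frozenset(bound),
    )


def prioritize_tfs(
    summaries,
    alpha: float = 0.05,
) -> tuple[list[TFBindingSummary], OutlierReport]:
    """Rank TFs by battery fraction and flag regression outliers.

    Fits OLS of battery_genes_bound on total_peaks across TFs and computes
    externally studentized residuals; a TF is flagged when its |residual|
    exceeds the two-sided t critical value at the Bonferroni-adjusted level
    ``alpha / n_TFs``.
    """
    summaries = list(summaries)
    n = len(summaries)
    if n < 3:
        raise ValueError("need at least 3 TF summaries for the regression")
    x = np.array([s.total_peaks for s in summaries], dtype=float)
    y = np.array([s.battery_genes_bound for s in summaries], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in total peak counts")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    influence = OLSInfluence(fit)
    df = n - 3  # n - params(2) - 1 for the deleted observation
    if df > 0:
        resid = influence.resid_studentized_external
        crit = sps.t.ppf(1 - alpha / (2 * n), df)
    else:
        # n == 3: external studentization has no residual df; fall back to
        # internal studentization with a normal reference
        resid = influence.resid_studentized_internal
        crit = sps.norm.ppf(1 - alpha / (2 * n))
    flagged = np.abs(resid) > crit
    report = OutlierReport(
        table=pd.DataFrame(
            {
                "tf_name": [s.tf_name for s in summaries],
                "total_peaks": x.astype(int),
                "battery_genes_bound": y.astype(int),
                "residual": resid,
                "flagged": flagged,
            }
        ),
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        critical_value=float(crit),
    )
    ranking = sorted(summaries, key=lambda s: (-s.battery_fraction, s.tf_name))
    return ranking, report
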