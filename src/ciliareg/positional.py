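"""Positional motif statistics over ChIP-seq peaks.

Three analyses live here:

* **Central enrichment** — fixed-length sequence windows centred on each peak
  are scanned with a PWM; per window only the single best-scoring site (both
  strands) is kept, and windows whose best score clears the threshold count as
  matches.  Under the null the best site falls uniformly over the window, so for
  a central region of width ``w`` the number of best sites inside it is
  binomial with success probability w / (number of possible site positions).
  The reported p-value is the minimum binomial upper tail over a grid of
  candidate central widths, Bonferroni-multiplied by the grid size.

* **Motif-to-peak distances** — distance from each motif instance (e.g. X-box)
  midpoint to the centre of the nearest peak, and the fraction falling under a
  cutoff (default 600 bp).

* **Dual-signature classification** — set algebra partitioning a gene battery
  into genes with both a motif and a binding event, either one alone, or
  neither.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import logger
from .battery import CATEGORIES, GeneBattery
from .peaks import PeakSet
from .seqmotif import PWM, best_match_score

DEFAULT_CENTRAL_WIDTHS = tuple(range(20, 201, 20))


@dataclass(frozen=True)
class PeakWindow:
    peak_id: str
    chrom: str
    center: int
    sequence: str


@dataclass
class CentralEnrichmentResult:
    n_windows: int
    n_with_match: int
    match_fraction: float
    best_central_width: int
    central_p: float
    n_central: int
    site_position_histogram: np.ndarray  # best-site centre offsets from window centre


@dataclass
class DistanceProfile:
    distances: np.ndarray          # per motif instance; inf when no peak on chrom
    cutoff: int
    fraction_within: float
    n_unmatched: int               # instances on peak-free chromosomes


@dataclass
class SignatureTable:
    classes: dict[str, str]        # gene_id -> class
    table: pd.DataFrame            # per-class counts, overall and per category

    CLASSES = ("xbox_and_peak", "peak_only", "xbox_only", "neither")

    def count(self, cls: str) -> int:
        return sum(1 for c in self.classes.values() if c == cls)

    def fraction(self, cls: str) -> float:
        return self.count(cls) / len(self.classes) if self.classes else 0.0


def peak_windows(
    peaks: PeakSet,
    genome: dict[str, str],
    half_width: int = 210,
) -> list[PeakWindow]:
    """Equal-length sequence windows ``[center - hw, center + hw)`` around peak
    centres (summit when present, else midpoint).  Windows overhanging a
    chromosome edge are excluded, with the exclusion count logged."""
    windows = []
    n_excluded = 0
    for i, p in enumerate(peaks):
        if p.chrom not in genome:
            raise KeyError(f"chromosome {p.chrom!r} not in genome")
        chrom_seq = genome[p.chrom]
        c = p.anchor
        lo, hi = c - half_width, c + half_width
        if lo < 0 or hi > len(chrom_seq):
            n_excluded += 1
            continue
        windows.append(PeakWindow(f"{peaks.tf_name}_{i}", p.chrom, c, chrom_seq[lo:hi]))
    if n_excluded:
        logger.warning("%d window(s) excluded at chromosome edges", n_excluded)
    return windows


def central_enrichment(
    pwm: PWM,
    windows,
    threshold: float | None = None,
    threshold_fraction: float | None = None,
    central_widths=DEFAULT_CENTRAL_WIDTHS,
) -> CentralEnrichmentResult:
    """Best-site central enrichment of a motif within peak windows."""
    windows = list(windows)
    if not windows:
        raise ValueError("no windows supplied")
    win_len = len(windows[0].sequence)
    if any(len(w.sequence) != win_len for w in windows):
        raise ValueError("windows must all have the same length")
    if win_len < pwm.width:
        raise ValueError("windows shorter than the motif")
    central_widths = [int(w) for w in central_widths]
    if any(w % 2 or w > win_len for w in central_widths):
        raise ValueError("central widths must be even and <= window length")
    if threshold is None:
        frac = 0.8 if threshold_fraction is None else threshold_fraction
        threshold = frac * pwm.max_score

    n_positions = win_len - pwm.width + 1
    # best-site centre offset from the window centre, for windows with a match
    offsets = []
    n_scoreable = 0
    for w in windows:
        score, off, _strand = best_match_score(pwm, w.sequence)
        if score is None:
            continue
        n_scoreable += 1
        if score >= threshold:
            site_center = off + pwm.width / 2.0
            offsets.append(site_center - win_len / 2.0)
    if n_scoreable == 0:
        raise ValueError("no window with any scoreable position")
    offsets = np.asarray(offsets)
    n_match = offsets.size

    best_p, best_w, best_k = 1.0, central_widths[0], 0
    for w in central_widths:
        k = int(np.sum(np.abs(offsets) <= w / 2.0))
        p_success = min(1.0, w / n_positions)
        p = float(stats.binom.sf(k - 1, n_match, p_success)) if n_match else 1.0
        if p < best_p:
            best_p, best_w, best_k = p, w, k
    central_p = min(1.0, best_p * len(central_widths))
    return CentralEnrichmentResult(
        n_windows=len(windows),
        n_with_match=n_match,
        match_fraction=n_match / len(windows),
        best_central_width=best_w,
        central_p=central_p,
        n_central=best_k,
        site_position_histogram=offsets,
    )


def xbox_peak_distance(
    xboxes,
    peaks: PeakSet,
    cutoff: int = 600,
    exclude_unmatched: bool = False,
) -> DistanceProfile:
    """Distance from each motif-interval midpoint to the nearest peak centre.

    ``xboxes`` is an iterable of (chrom, start, end) intervals, 0-based
    half-open.  Instances on chromosomes with no peaks receive an infinite
    distance; they are dropped from the denominator of ``fraction_within`` when
    ``exclude_unmatched`` is true, else counted as not-within.
    """
    if len(peaks) == 0:
        raise ValueError("empty peak set")
    centers: dict[str, np.ndarray] = {}
    for p in peaks:
        centers.setdefault(p.chrom, []).append(p.anchor)
    centers = {c: np.sort(np.asarray(v)) for c, v in centers.items()}

    xboxes = list(xboxes)
    dists = np.empty(len(xboxes))
    for i, (chrom, start, end) in enumerate(xboxes):
        cs = centers.get(chrom)
        if cs is None:
            dists[i] = np.inf
            continue
        mid = (start + end) / 2.0
        j = np.searchsorted(cs, mid)
        candidates = [abs(mid - cs[k]) for k in (j - 1, j) if 0 <= k < cs.size]
        dists[i] = min(candidates)
    n_unmatched = int(np.isinf(dists).sum())
    denom = dists.size - n_unmatched if exclude_unmatched else dists.size
    within = int(np.sum(dists < cutoff))
    return DistanceProfile(
        distances=dists,
        cutoff=cutoff,
        fraction_within=within / denom if denom else 0.0,
        n_unmatched=n_unmatched,
    )


def classify_signatures(
    battery: GeneBattery,
    xbox_genes,
    bound_genes,
) -> SignatureTable:
    """Partition battery genes into the four motif x binding classes.

    Gene ids in the input sets that are not battery members are ignored with a
    logged count.
    """
    battery_ids = battery.gene_ids()
    xbox_genes, bound_genes = set(xbox_genes), set(bound_genes)
    extraneous = (xbox_genes | bound_genes) - battery_ids
    if extraneous:
        logger.info("%d gene id(s) outside the battery ignored", len(extraneous))
    classes = {}
    for g in battery:
        has_x, has_p = g.gene_id in xbox_genes, g.gene_id in bound_genes
        if has_x and has_p:
            cls = "xbox_and_peak"
        elif has_p:
            cls = "peak_only"
        elif has_x:
            cls = "xbox_only"
        else:
            cls = "neither"
        classes[g.gene_id] = cls

    rows = []
    for scope in ("all",) + CATEGORIES:
        ids = battery_ids if scope == "all" else battery.by_category(scope)
        row = {"scope": scope, "n": len(ids)}
        for cls in SignatureTable.CLASSES:
            row[cls] = sum(1 for g in ids if classes[g] == cls)
        rows.append(row)
    return SignatureTable(classes=classes, table=pd.DataFrame(rows))
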