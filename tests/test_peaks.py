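"""narrowPeak parsing, peak-to-gene annotation, battery binding and TF
prioritization with outlier detection."""

import numpy as np
import pytest

from ciliareg.battery import BatteryGene, GeneBattery
from ciliareg.peaks import (
    Peak,
    PeakAnnotation,
    PeakSet,
    TFBindingSummary,
    annotate_peaks,
    battery_binding,
    feature_distribution,
    prioritize_tfs,
    read_narrowpeak,
)
from conftest import make_model


# ---------------------------------------------------------------------------
# narrowPeak I/O
# ---------------------------------------------------------------------------

def write_np(tmp_path, lines, name="peaks.narrowPeak"):
    path = tmp_path / name
    path.write_text("\n".join(lines) + "\n")
    return path


def test_read_narrowpeak_toy(tmp_path):
    path = write_np(tmp_path, [
        "chr1\t100\t300\tp1\t500\t.\t8.1\t-1\t-1\t50",
        "chr1\t1000\t1200\tp2\t700\t.\t9.0\t-1\t-1\t-1",
        "chr2\t10\t60\tp3\t100\t.\t1.0\t-1\t-1\t25",
    ])
    ps = read_narrowpeak(path, tf_name="toy")
    assert len(ps) == 3
    p1 = ps.peaks[0]
    assert (p1.chrom, p1.start, p1.end, p1.summit_offset) == ("chr1", 100, 300, 50)
    assert p1.anchor == 150
    # summit sentinel -1 falls back to midpoint
    p2 = ps.peaks[1]
    assert p2.summit_offset == -1 and p2.anchor == 1100


def test_read_narrowpeak_malformed(tmp_path):
    with pytest.raises(ValueError, match="columns"):
        read_narrowpeak(write_np(tmp_path, ["chr1\t1\t2\tx\t0"], "a.np"))
    with pytest.raises(ValueError, match="end <= start"):
        read_narrowpeak(write_np(tmp_path, ["chr1\t5\t5\tx\t0\t.\t1\t-1\t-1\t-1"], "b.np"))
    with pytest.raises(ValueError, match="non-numeric"):
        read_narrowpeak(write_np(tmp_path, ["chr1\tX\t5\tx\t0\t.\t1\t-1\t-1\t-1"], "c.np"))


def test_peak_validation():
    with pytest.raises(ValueError):
        Peak("chr1", 10, 5)
    with pytest.raises(ValueError):
        Peak("chr1", 10, 20, summit_offset=15)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def test_promoter_annotation_hand_case():
    m = make_model(gene_id="g1", strand="+", tss=10000)
    ps = PeakSet("tf", [Peak("chr1", 8900, 9100, summit_offset=100)])  # anchor 9000
    [ann] = annotate_peaks(ps, [m])
    assert ann.feature == "promoter"
    assert ann.gene_id == "g1"
    assert ann.distance_to_tss == -1000


def test_promoter_window_is_strand_aware():
    m = make_model(gene_id="gm", strand="-", tss=10000)
    # anchor 10500 is 500 bp upstream of a minus-strand TSS at 10000
    ps = PeakSet("tf", [Peak("chr1", 10400, 10600)])
    [ann] = annotate_peaks(ps, [m])
    assert ann.feature == "promoter" and ann.distance_to_tss == -500


def test_equidistant_tie_breaks_lexicographically():
    a = make_model(gene_id="gb", strand="+", tss=1000)
    b = make_model(gene_id="ga", strand="+", tss=3000)
    ps = PeakSet("tf", [Peak("chr1", 1990, 2010)])  # anchor 2000, 1000 bp from both
    [ann] = annotate_peaks(ps, [a, b])
    assert ann.gene_id == "ga"


def test_peak_on_geneless_chromosome_is_intergenic_sentinel():
    m = make_model(gene_id="g1", chrom="chr1", tss=1000)
    ps = PeakSet("tf", [Peak("chr9", 500, 700)])
    [ann] = annotate_peaks(ps, [m])
    assert ann.feature == "intergenic"
    assert ann.gene_id is None and ann.distance_to_tss is None


def test_feature_precedence_and_downstream():
    m = make_model(gene_id="g1", strand="+", tss=10000, tls=10150,
                   start=10000, end=12000)
    anns = annotate_peaks(
        PeakSet("tf", [
            Peak("chr1", 11390, 11410),   # anchor 11400: genic (past +1000 window)
            Peak("chr1", 13090, 13110),   # anchor 13100: 1100 bp past gene end
            Peak("chr1", 99000, 99100),   # far away: intergenic
        ]),
        [m],
    )
    assert [a.feature for a in anns] == ["genic", "downstream", "intergenic"]
    assert all(a.gene_id == "g1" for a in anns)


def test_annotation_invariant_under_peak_order():
    models = [make_model(gene_id=f"g{i}", tss=3000 + 5000 * i) for i in range(5)]
    peaks = [Peak("chr1", 2500 + 4000 * i, 2700 + 4000 * i) for i in range(6)]
    fwd = annotate_peaks(PeakSet("tf", peaks), models)
    rev = annotate_peaks(PeakSet("tf", peaks[::-1]), models)
    key = lambda a: (a.peak.start, a.feature, a.gene_id)
    assert sorted(map(key, fwd)) == sorted(map(key, rev))


def test_promoter_calls_match_brute_force_all_pairs():
    """Promoter feature calls reproduce an exhaustive peak x gene interval
    check on a random instance."""
    rng = np.random.default_rng(3)
    models = []
    pos = 3000
    for i in range(50):
        strand = "+" if rng.random() < 0.5 else "-"
        models.append(make_model(gene_id=f"g{i:02d}", strand=strand, tss=pos))
        pos += int(rng.integers(3000, 9000))
    peaks = [Peak("chr1", int(s), int(s) + 200)
             for s in rng.integers(0, pos, size=100)]
    anns = annotate_peaks(PeakSet("tf", peaks), models, tss_window=(2000, 1000))
    for ann in anns:
        anchor = ann.peak.anchor
        hits = []
        for m in models:
            d = anchor - m.tss if m.strand == "+" else m.tss - anchor
            if -2000 <= d < 1000:
                hits.append((abs(d), m.gene_id))
        if hits:
            assert ann.feature == "promoter"
            assert ann.gene_id == min(hits)[1]
        else:
            assert ann.feature != "promoter"


def test_empty_model_set_raises():
    with pytest.raises(ValueError):
        annotate_peaks(PeakSet("tf", [Peak("chr1", 0, 10)]), [])


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def toy_annotation(gene_id, feature="promoter", start=0):
    return PeakAnnotation(Peak("chr1", start, start + 10), feature, gene_id, 0)


def test_feature_distribution_sums_to_one():
    anns = [toy_annotation("a"), toy_annotation("b"),
            toy_annotation(None, "intergenic"), toy_annotation(None, "intergenic")]
    dist = feature_distribution(anns)
    assert dist["promoter"] == 0.5 and dist["intergenic"] == 0.5
    assert sum(dist.values()) == pytest.approx(1.0)
    assert feature_distribution([toy_annotation("a")])["promoter"] == 1.0


def test_battery_binding_counts_each_gene_once():
    battery = GeneBattery([BatteryGene("a", "core"), BatteryGene("b", "core"),
                           BatteryGene("c", "subtype"), BatteryGene("d", "subtype")])
    anns = [toy_annotation("a"), toy_annotation("a", start=50),
            toy_annotation("c"), toy_annotation("zzz")]
    s = battery_binding(anns, battery, tf_name="tf")
    assert s.battery_genes_bound == 2
    assert s.battery_fraction == 0.5
    assert s.core_fraction == 0.5 and s.subtype_fraction == 0.5


def test_battery_binding_no_peaks_all_zero():
    battery = GeneBattery([BatteryGene("a", "core")])
    s = battery_binding([], battery, tf_name="tf", total_peaks=0)
    assert s.battery_fraction == 0 and s.core_fraction == 0


def test_battery_binding_feature_filter():
    battery = GeneBattery([BatteryGene("a", "core")])
    anns = [toy_annotation("a", feature="genic")]
    assert battery_binding(anns, battery).battery_genes_bound == 0
    assert battery_binding(anns, battery,
                           features=("promoter", "genic")).battery_genes_bound == 1


# ---------------------------------------------------------------------------
# prioritization
# ---------------------------------------------------------------------------

def summary(name, total, bound, frac=None):
    return TFBindingSummary(tf_name=name, total_peaks=total,
                            battery_genes_bound=bound,
                            battery_fraction=frac if frac is not None else bound / 163,
                            core_fraction=0, subtype_fraction=0)


def test_planted_outlier_uniquely_flagged():
    rng = np.random.default_rng(9)
    summaries = []
    for i in range(20):
        x = int(rng.integers(500, 5000))
        summaries.append(summary(f"tf{i:02d}", x, round(0.01 * x)))
    summaries.append(summary("REG", 3000, round(0.01 * 3000) + 50))
    _, report = prioritize_tfs(summaries)
    assert report.flagged_tfs() == ["REG"]


def test_collinear_points_no_flags():
    summaries = [summary(f"tf{i}", 1000 * (i + 1), 10 * (i + 1)) for i in range(5)]
    _, report = prioritize_tfs(summaries)
    assert report.flagged_tfs() == []


def test_prioritize_requires_three_summaries():
    with pytest.raises(ValueError):
        prioritize_tfs([summary("a", 10, 1), summary("b", 20, 2)])
    with pytest.raises(ValueError, match="variance"):
        prioritize_tfs([summary(c, 100, i) for i, c in enumerate("abc")])


def test_ranking_is_by_battery_fraction():
    summaries = [summary("low", 100, 5, frac=0.05),
                 summary("high", 150, 50, frac=0.5),
                 summary("mid", 200, 20, frac=0.2)]
    ranking, _ = prioritize_tfs(summaries)
    assert [s.tf_name for s in ranking] == ["high", "mid", "low"]


def test_null_tfs_rarely_flagged():
    """With all TFs sharing one binding rate (constant-variance scatter around
    the shared line, the regression's own null), the per-experiment family-wise
    flag rate stays near the nominal 5% level."""
    rng = np.random.default_rng(21)
    n_flagged = 0
    for _ in range(200):
        summaries = []
        for i in range(20):
            x = int(rng.integers(500, 5000))
            bound = max(0, round(0.01 * x + rng.normal(0, 4)))
            summaries.append(summary(f"tf{i:02d}", x, bound))
        _, report = prioritize_tfs(summaries)
        n_flagged += bool(report.flagged_tfs())
    # binomial(200, 0.05) three-sigma upper bound
    assert n_flagged <= 10 + 3 * np.sqrt(200 * 0.05 * 0.95)
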