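"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the study system: a nematode-scale genome (six
chromosomes, ~100 Mb, AT-rich i.i.d. sequence) carrying ~20,000 non-overlapping
gene models, among them a 163-gene ciliome battery split 73/68/13/9 across the
core / subtype / broad / male categories; X-box-like motif instances planted in
battery promoters with category-specific probabilities; a collection of ChIP-seq
peak sets in which one designated regulator concentrates peaks in battery-gene
TSS windows (per-category bound probabilities default to the fractions the
battery screen is expected to produce: 75% of core, 22% of subtype, ~49%
overall) while background TFs place peaks uniformly; negative-binomial
single-cell counts with the regulator enriched fivefold in a target cell class
and a coupled core-gene set for correlation profiling; and per-animal
reporter-neuron counts under configurable multiplicative or epistatic genotype
effects.

Every generator returns a machine-readable truth table alongside its data, and
all randomness flows from the config seed through per-stage child streams, so
regeneration under the same seed is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .battery import BatteryGene, GeneBattery
from .genstats import ReporterCounts
from .peaks import Peak, PeakSet
from .scexpr import CellByGeneMatrix
from .seqmotif import PWM, GeneModel, build_pwm
from ._utils import BASES, reverse_complement

# C. elegans-like chromosome lengths (bp)
WORM_CHROM_LENGTHS = {
    "chrI": 15_000_000,
    "chrII": 15_300_000,
    "chrIII": 13_800_000,
    "chrIV": 17_500_000,
    "chrV": 20_900_000,
    "chrX": 17_700_000,
}

# canonical C. elegans RFX (DAF-19) X-box consensus; this is a synthetic
# X-box-like matrix built from the consensus, not a database PWM
XBOX_CONSENSUS = "GTTGCCATGGCAAC"
FKH_CONSENSUS = "GTAAACA"


def consensus_count_matrix(consensus: str, weight: float = 0.85, total: int = 100) -> np.ndarray:
    """Count matrix concentrated on a consensus string: the consensus base gets
    ``weight`` of each column's mass, the rest is spread evenly."""
    mat = np.full((len(consensus), 4), total * (1 - weight) / 3)
    for i, base in enumerate(consensus):
        mat[i, BASES.index(base)] = total * weight
    return mat


def default_xbox_pwm(pseudocount: float = 0.01) -> PWM:
    """Synthetic X-box-like PWM (RFX binding-site emulation)."""
    return build_pwm(consensus_count_matrix(XBOX_CONSENSUS), pseudocount=pseudocount,
                     name="xbox_synthetic")


def default_fkh_pwm(pseudocount: float = 0.01) -> PWM:
    """Synthetic Forkhead-like PWM."""
    return build_pwm(consensus_count_matrix(FKH_CONSENSUS), pseudocount=pseudocount,
                     name="fkh_synthetic")


@dataclass
class SynthConfig:
    """All generator knobs.  Defaults encode the emulated study conditions."""

    seed: int = 1

    # genome & genes
    chrom_lengths: dict = field(default_factory=lambda: dict(WORM_CHROM_LENGTHS))
    gc_content: float = 0.355
    n_genes: int = 20_000
    battery_counts: dict = field(
        default_factory=lambda: {"core": 73, "subtype": 68, "broad": 13, "male": 9}
    )
    utr_len: int = 150
    gene_len_range: tuple = (1000, 3000)
    promoter_len: int = 700

    # motif planting in battery promoters (per category)
    xbox_prob: dict = field(
        default_factory=lambda: {"core": 0.83, "subtype": 0.27, "broad": 0.58, "male": 0.58}
    )

    # peak sets
    regulator_name: str = "REG"
    regulator_n_peaks: int = 5035
    bound_prob: dict = field(
        default_factory=lambda: {"core": 0.75, "subtype": 0.22, "broad": 0.46, "male": 0.46}
    )
    n_background_tfs: int = 20
    background_peak_range: tuple = (500, 4000)
    peak_len_range: tuple = (300, 500)
    tss_window: tuple = (2000, 1000)
    co_binding_fraction: float = 0.5   # bound x-box genes whose peak centres on the X-box
    co_binding_jitter_sd: float = 200.0
    peak_motif_prob: float = 0.20      # X-box planted at a regulator peak centre
    peak_motif_jitter_sd: float = 60.0

    # single-cell matrix
    sc_classes: dict = field(
        default_factory=lambda: {"ciliated": 1000, "other_neuron": 2000, "non_neuronal": 2000}
    )
    sc_target_class: str = "ciliated"
    sc_regulator: str = "fkh-8"
    sc_n_null_tfs: int = 49
    sc_set_sizes: dict = field(
        default_factory=lambda: {"core": 40, "subtype": 30, "panneuronal": 20, "ubiquitous": 20}
    )
    sc_n_background: int = 400
    sc_base_mean: float = 0.4
    sc_regulator_fold: float = 8.0
    sc_nb_dispersion: float = 0.5      # var = mu + dispersion * mu^2
    sc_coupling: float = 0.8           # latent-factor coupling of core genes to the regulator
    sc_depth_sd: float = 0.3           # lognormal sigma of per-cell depth

    # reporter counts
    reporter_reference: str = "daf-12"
    reporter_ref_mean: float = 60.0
    reporter_multipliers: dict = field(
        default_factory=lambda: {"daf-12;fkh-8": 0.5, "daf-12;daf-19": 0.15}
    )
    reporter_interaction: float = 1.0  # 1 = multiplicative null; <1 = synergistic loss
    reporter_n_animals: int = 10
    reporter_noise: str = "poisson"    # or "nb"
    reporter_nb_dispersion: float = 0.05

    def __post_init__(self):
        for probs in (self.xbox_prob, self.bound_prob):
            for v in probs.values():
                if not 0 <= v <= 1:
                    raise ValueError("probabilities must be in [0, 1]")
        for L in self.chrom_lengths.values():
            if L < 10_000:
                raise ValueError("chromosome lengths must be >= 10 kb")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic child stream per generator stage."""
        return np.random.default_rng([self.seed, stream])

    @classmethod
    def desk_scale(cls, seed: int = 1, **overrides) -> "SynthConfig":
        """A small configuration for fast desk runs and tests."""
        defaults = dict(
            chrom_lengths={"chr1": 3_000_000, "chr2": 3_000_000},
            n_genes=500,
            battery_counts={"core": 20, "subtype": 15, "broad": 5, "male": 4},
            regulator_n_peaks=200,
            n_background_tfs=12,
            background_peak_range=(50, 400),
            sc_classes={"ciliated": 300, "other_neuron": 400, "non_neuronal": 400},
            sc_n_null_tfs=20,
            sc_n_background=150,
        )
        defaults.update(overrides)
        return cls(seed=seed, **defaults)


# ---------------------------------------------------------------------------
# genome + gene models + planted promoter motifs
# ---------------------------------------------------------------------------

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> bytearray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p)
    return bytearray(_BASE_BYTES[codes].tobytes())


def synth_genome_and_genes(cfg: SynthConfig, xbox_pwm: PWM | None = None):
    """Generate (genome dict, gene models, battery, truth).

    Gene models are laid out on a jittered grid, non-overlapping, on random
    strands.  Battery genes are a random subset; X-box instances (the PWM's
    consensus string, in promoter orientation) are written into battery
    promoters with category-specific probability, at a uniform offset.  The
    truth table records the genomic coordinates and strand of every planted
    instance.
    """
    rng = cfg.rng(1)
    if xbox_pwm is None:
        xbox_pwm = default_xbox_pwm()
    consensus = xbox_pwm.consensus()
    width = len(consensus)

    chroms = {}
    models: list[GeneModel] = []
    total_len = sum(cfg.chrom_lengths.values())
    n_battery = sum(cfg.battery_counts.values())
    if cfg.n_genes < n_battery:
        raise ValueError("n_genes smaller than the battery size")

    # genes per chromosome, proportional to length
    chrom_names = list(cfg.chrom_lengths)
    n_per_chrom = {c: max(1, round(cfg.n_genes * cfg.chrom_lengths[c] / total_len))
                   for c in chrom_names}

    gene_counter = 0
    edge_margin = 2500
    for chrom in chrom_names:
        L = cfg.chrom_lengths[chrom]
        chroms[chrom] = _random_sequence(rng, L, cfg.gc_content)
        n_i = n_per_chrom[chrom]
        spacing = (L - 2 * edge_margin) // n_i
        glen_hi = min(cfg.gene_len_range[1], max(cfg.gene_len_range[0] + 1, spacing - 10))
        for j in range(n_i):
            slot = edge_margin + j * spacing
            glen = int(rng.integers(cfg.gene_len_range[0], glen_hi))
            offset_hi = max(1, spacing - glen)
            start = slot + int(rng.integers(0, offset_hi))
            end = start + glen
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                tss, tls = start, start + cfg.utr_len
            else:
                tss, tls = end, end - cfg.utr_len
            models.append(GeneModel(
                gene_id=f"g{gene_counter:05d}", chrom=chrom, strand=strand,
                tss=tss, tls=tls, start=start, end=end,
            ))
            gene_counter += 1

    # battery assignment: random gene subset, renamed to battery ids
    battery_idx = rng.choice(len(models), size=n_battery, replace=False)
    categories = [c for c, n in cfg.battery_counts.items() for _ in range(n)]
    battery_genes = []
    for k, (idx, cat) in enumerate(zip(battery_idx, categories)):
        m = models[idx]
        gid = f"cil-{k + 1:03d}"
        models[idx] = GeneModel(gene_id=gid, chrom=m.chrom, strand=m.strand,
                                tss=m.tss, tls=m.tls, start=m.start, end=m.end)
        battery_genes.append(BatteryGene(gene_id=gid, category=cat))
    battery = GeneBattery(battery_genes, name="synthetic_ciliome")
    model_by_id = {m.gene_id: m for m in models}

    # plant X-boxes in battery promoters
    planted = []
    for gene in battery_genes:
        if rng.random() >= cfg.xbox_prob[gene.category]:
            continue
        m = model_by_id[gene.gene_id]
        u = int(rng.integers(0, cfg.promoter_len - width + 1))  # offset within promoter
        if m.strand == "+":
            gpos = m.tls - cfg.promoter_len + u
            seq = consensus
        else:
            gpos = m.tls + cfg.promoter_len - u - width
            seq = reverse_complement(consensus)
        chroms[m.chrom][gpos : gpos + width] = seq.encode("ascii")
        planted.append({"gene_id": gene.gene_id, "category": gene.category,
                        "chrom": m.chrom, "start": gpos, "end": gpos + width,
                        "strand": m.strand, "context": "promoter"})

    genome = {c: bytes(b).decode("ascii") for c, b in chroms.items()}
    truth = {
        "planted_motifs": pd.DataFrame(
            planted, columns=["gene_id", "category", "chrom", "start", "end",
                              "strand", "context"]
        ),
        "consensus": consensus,
        "n_genes": len(models),
    }
    return genome, models, battery, truth


# ---------------------------------------------------------------------------
# peak sets
# ---------------------------------------------------------------------------

def synth_peaksets(
    cfg: SynthConfig,
    models,
    battery: GeneBattery,
    genome: dict | None = None,
    motif_truth: pd.DataFrame | None = None,
):
    """Generate (list of PeakSet, truth).

    The designated regulator binds each battery gene with its category's bound
    probability (one peak anchored inside the gene's TSS window); when the gene
    also carries a planted promoter X-box, a configurable fraction of those
    peaks centre on the X-box (co-binding).  Because TSS windows of neighbouring
    genes overlap, each designated anchor is re-drawn until the nearest-TSS
    assignment rule resolves to the designated gene (a gene for which no such
    position is found after bounded retries is dropped from the bound truth).
    The regulator's remaining peaks are uniform but rejected out of all battery
    TSS windows, so the truth table of bound battery genes is exact.  Background TFs place peaks uniformly.  When
    ``genome`` is given (as mutable sequences are needed, it is edited in
    place via re-built strings), X-box instances are additionally planted near
    regulator peak centres with probability ``peak_motif_prob`` to emulate
    genome-wide motif co-occurrence; ``motif_truth`` supplies the promoter
    X-box coordinates used for co-binding.
    """
    rng = cfg.rng(2)
    models = list(models)
    model_by_id = {m.gene_id: m for m in models}
    up, down = cfg.tss_window
    chrom_names = sorted({m.chrom for m in models})
    chrom_lengths = dict(cfg.chrom_lengths)

    # battery TSS windows, for rejection sampling of non-target peaks
    battery_windows: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    for g in battery:
        m = model_by_id[g.gene_id]
        lo = m.tss - up if m.strand == "+" else m.tss - down + 1
        hi = m.tss + down if m.strand == "+" else m.tss + up + 1
        battery_windows[m.chrom].append((lo, hi))
    win_arrays = {
        c: (np.array(sorted(w)) if w else np.empty((0, 2), int))
        for c, w in battery_windows.items()
    }

    def in_battery_window(chrom: str, pos: int) -> bool:
        wins = win_arrays[chrom]
        if wins.size == 0:
            return False
        i = np.searchsorted(wins[:, 0], pos, side="right")
        for k in range(max(0, i - 3), i):
            if wins[k, 0] <= pos < wins[k, 1]:
                return True
        return False

    xbox_by_gene = {}
    if motif_truth is not None:
        for row in motif_truth.itertuples():
            xbox_by_gene[row.gene_id] = (row.start + row.end) // 2

    # per-chromosome TSS arrays to replicate the promoter-assignment rule
    tss_sorted: dict[str, tuple[np.ndarray, list]] = {}
    for c in chrom_names:
        ms = sorted((m for m in models if m.chrom == c), key=lambda m: m.tss)
        tss_sorted[c] = (np.array([m.tss for m in ms]), ms)

    def promoter_assignee(chrom: str, anchor: int):
        """Gene id the annotation rule would assign a promoter anchor to."""
        arr, ms = tss_sorted[chrom]
        lo = np.searchsorted(arr, anchor - max(up, down))
        hi = np.searchsorted(arr, anchor + max(up, down), side="right")
        hits = []
        for m in ms[lo:hi]:
            d = anchor - m.tss if m.strand == "+" else m.tss - anchor
            if -up <= d < down:
                hits.append((abs(d), m.gene_id))
        return min(hits)[1] if hits else None

    margin = 1000
    chrom_probs = np.array([chrom_lengths[c] for c in chrom_names], dtype=float)
    chrom_probs /= chrom_probs.sum()

    def uniform_center(avoid_battery: bool):
        while True:
            chrom = chrom_names[rng.choice(len(chrom_names), p=chrom_probs)]
            pos = int(rng.integers(margin, chrom_lengths[chrom] - margin))
            if not (avoid_battery and in_battery_window(chrom, pos)):
                return chrom, pos

    def make_peak(chrom: str, center: int) -> Peak:
        length = int(rng.integers(*cfg.peak_len_range))
        start = max(0, center - length // 2)
        end = min(chrom_lengths[chrom], start + length)
        return Peak(chrom, start, end, summit_offset=center - start,
                    score=float(rng.integers(100, 1000)))

    # --- regulator ---
    reg_peaks: list[Peak] = []
    bound_genes: list[str] = []
    co_bound: list[str] = []
    centers_for_planting: list[tuple[str, int]] = []
    for g in battery:
        if rng.random() >= cfg.bound_prob[g.category]:
            continue
        m = model_by_id[g.gene_id]
        want_cobind = (g.gene_id in xbox_by_gene
                       and rng.random() < cfg.co_binding_fraction)
        center = None
        for attempt in range(40):
            cobind = want_cobind and attempt < 20
            if cobind:
                c = int(xbox_by_gene[g.gene_id]
                        + rng.normal(0, cfg.co_binding_jitter_sd))
            else:
                d = int(rng.integers(-up + 50, down - 50))
                c = m.tss + d if m.strand == "+" else m.tss - d
            c = int(np.clip(c, margin, chrom_lengths[m.chrom] - margin))
            if promoter_assignee(m.chrom, c) == g.gene_id:
                center = c
                if cobind:
                    co_bound.append(g.gene_id)
                break
        if center is None:
            continue  # no position assigns to this gene; leave it unbound
        bound_genes.append(g.gene_id)
        reg_peaks.append(make_peak(m.chrom, center))
    n_rest = max(0, cfg.regulator_n_peaks - len(reg_peaks))
    for _ in range(n_rest):
        chrom, pos = uniform_center(avoid_battery=True)
        reg_peaks.append(make_peak(chrom, pos))
        centers_for_planting.append((chrom, pos))

    # plant X-boxes near regulator peak centres (genome-wide co-occurrence)
    peak_motifs = []
    if genome is not None and cfg.peak_motif_prob > 0:
        pwm = default_xbox_pwm()
        consensus = pwm.consensus()
        width = len(consensus)
        editable = {c: bytearray(s, "ascii") for c, s in genome.items()}
        for chrom, pos in centers_for_planting:
            if rng.random() >= cfg.peak_motif_prob:
                continue
            site_center = int(pos + rng.normal(0, cfg.peak_motif_jitter_sd))
            gpos = site_center - width // 2
            if gpos < 0 or gpos + width > chrom_lengths[chrom]:
                continue
            seq = consensus if rng.random() < 0.5 else reverse_complement(consensus)
            editable[chrom][gpos : gpos + width] = seq.encode("ascii")
            peak_motifs.append({"chrom": chrom, "start": gpos, "end": gpos + width,
                                "peak_center": pos})
        for chrom in editable:
            genome[chrom] = bytes(editable[chrom]).decode("ascii")

    peaksets = [PeakSet(tf_name=cfg.regulator_name, peaks=reg_peaks,
                        dataset_id="synthetic_regulator")]

    # --- background TFs ---
    for t in range(cfg.n_background_tfs):
        n_peaks = int(rng.integers(*cfg.background_peak_range))
        tf_peaks = []
        for _ in range(n_peaks):
            chrom, pos = uniform_center(avoid_battery=False)
            tf_peaks.append(make_peak(chrom, pos))
        peaksets.append(PeakSet(tf_name=f"TF{t + 1:02d}", peaks=tf_peaks,
                                dataset_id=f"synthetic_bg_{t + 1}"))

    truth = {
        "bound_battery_genes": sorted(bound_genes),
        "co_bound_genes": sorted(co_bound),
        "peak_center_motifs": pd.DataFrame(
            peak_motifs, columns=["chrom", "start", "end", "peak_center"]
        ),
        "regulator": cfg.regulator_name,
    }
    return peaksets, truth


# ---------------------------------------------------------------------------
# single-cell matrix
# ---------------------------------------------------------------------------

def synth_sc_matrix(cfg: SynthConfig):
    """Generate (CellByGeneMatrix, truth).

    Counts are negative binomial (var = mu + dispersion * mu^2) around per-gene
    base means modulated by per-cell depth.  Planted effects are defined on the
    depth-normalized scale: after applying class effects, per-class expected
    totals over the non-regulator genes are rebalanced to a common value, so a
    regulator planted at fold f really is f-fold enriched after per-cell
    normalization rather than being diluted by the compositional shift of the
    other class-biased genes.  The regulator's mean is multiplied by
    ``sc_regulator_fold`` in the target class; core-set genes and the regulator
    share a per-cell latent factor inside the target class (strength
    ``sc_coupling``) so correlation profiling has planted positives.  Gene sets:
    core and subtype (battery-like), panneuronal (neurons only), ubiquitous,
    plus a background filler population expressed uniformly across classes.
    """
    rng = cfg.rng(3)
    if len(cfg.sc_classes) < 2:
        raise ValueError("need at least 2 cell classes")
    classes = []
    for name, n in cfg.sc_classes.items():
        classes += [name] * n
    n_cells = len(classes)
    class_arr = np.array(classes)
    is_target = class_arr == cfg.sc_target_class
    is_neuron = np.isin(class_arr, [cfg.sc_target_class, "other_neuron"])

    gene_sets = {
        "core": [f"core-{i:03d}" for i in range(cfg.sc_set_sizes["core"])],
        "subtype": [f"sub-{i:03d}" for i in range(cfg.sc_set_sizes["subtype"])],
        "panneuronal": [f"pan-{i:03d}" for i in range(cfg.sc_set_sizes["panneuronal"])],
        "ubiquitous": [f"ubi-{i:03d}" for i in range(cfg.sc_set_sizes["ubiquitous"])],
    }
    candidates = [cfg.sc_regulator] + [f"tf-{i:03d}" for i in range(cfg.sc_n_null_tfs)]
    background = [f"bg-{i:03d}" for i in range(cfg.sc_n_background)]
    gene_ids = candidates + [g for ids in gene_sets.values() for g in ids] + background
    n_genes = len(gene_ids)

    base = rng.lognormal(np.log(cfg.sc_base_mean), 0.4, size=n_genes)
    mu = np.tile(base, (n_cells, 1))

    idx = {g: j for j, g in enumerate(gene_ids)}
    # core/subtype genes concentrated in the target class, panneuronal in neurons
    for g in gene_sets["core"]:
        mu[~is_target, idx[g]] *= 0.1
        mu[is_target, idx[g]] *= 3.0
    for g in gene_sets["subtype"]:
        mu[~is_target, idx[g]] *= 0.2
    for g in gene_sets["panneuronal"]:
        mu[~is_neuron, idx[g]] *= 0.05
        mu[is_neuron, idx[g]] *= 2.0
    for g in gene_sets["ubiquitous"]:
        mu[:, idx[g]] *= 4.0

    # rebalance per-class expected totals (regulator excluded) so planted folds
    # survive counts-per-10k normalization
    reg_j = idx[cfg.sc_regulator]
    other_cols = np.array([j for j in range(n_genes) if j != reg_j])
    class_totals = {}
    for cls in dict.fromkeys(classes):
        rows = class_arr == cls
        class_totals[cls] = mu[np.ix_(rows, other_cols)].sum(axis=1).mean()
    t_ref = float(np.mean(list(class_totals.values())))
    for cls, tot in class_totals.items():
        mu[np.ix_(class_arr == cls, other_cols)] *= t_ref / tot

    # regulator enriched in the target class
    mu[is_target, reg_j] *= cfg.sc_regulator_fold

    # latent factor couples the regulator and the core set inside the target class
    if cfg.sc_coupling > 0:
        z = rng.gamma(shape=4.0, scale=0.25, size=int(is_target.sum()))  # mean 1
        factor = 1 + cfg.sc_coupling * (z - 1)
        coupled = [cfg.sc_regulator] + gene_sets["core"]
        for g in coupled:
            mu[is_target, idx[g]] *= factor

    depth = rng.lognormal(0.0, cfg.sc_depth_sd, size=n_cells)
    mu *= depth[:, None]

    if cfg.sc_nb_dispersion > 0:
        theta = 1.0 / cfg.sc_nb_dispersion
        counts = rng.negative_binomial(theta, theta / (theta + mu))
    else:
        counts = rng.poisson(mu)

    matrix = CellByGeneMatrix(
        counts=counts.astype(np.int64),
        cell_ids=[f"cell{i:05d}" for i in range(n_cells)],
        gene_ids=gene_ids,
        cell_class=classes,
    )
    truth = {
        "regulator": cfg.sc_regulator,
        "fold": cfg.sc_regulator_fold,
        "target_class": cfg.sc_target_class,
        "coupled_genes": [cfg.sc_regulator] + gene_sets["core"],
        "gene_sets": gene_sets,
        "candidates": candidates,
    }
    return matrix, truth


# ---------------------------------------------------------------------------
# reporter counts
# ---------------------------------------------------------------------------

def synth_reporter_counts(cfg: SynthConfig):
    """Generate (list of ReporterCounts, truth).

    Counts are Poisson (or NB) around reference_mean x genotype multiplier.
    The triple-mutant multiplier is the product of the two double-mutant
    multipliers times the interaction coefficient; interaction 1 is the
    multiplicative null, < 1 a synergistic loss.
    """
    rng = cfg.rng(4)
    if cfg.reporter_ref_mean <= 0:
        raise ValueError("reference mean must be positive")
    doubles = list(cfg.reporter_multipliers.items())
    if len(doubles) != 2:
        raise ValueError("exactly two double-mutant multipliers expected")
    (name_a, m_a), (name_b, m_b) = doubles
    triple_name = ";".join(sorted(set(
        part for name in (name_a, name_b) for part in name.split(";")
    )))
    multipliers = {
        cfg.reporter_reference: 1.0,
        name_a: m_a,
        name_b: m_b,
        triple_name: m_a * m_b * cfg.reporter_interaction,
    }

    def draw(mean: float) -> np.ndarray:
        if cfg.reporter_noise == "poisson":
            return rng.poisson(mean, size=cfg.reporter_n_animals)
        theta = 1.0 / cfg.reporter_nb_dispersion
        return rng.negative_binomial(theta, theta / (theta + mean),
                                     size=cfg.reporter_n_animals)

    groups = [
        ReporterCounts(genotype=name, values=draw(cfg.reporter_ref_mean * mult))
        for name, mult in multipliers.items()
    ]
    truth = {
        "multipliers": multipliers,
        "interaction": cfg.reporter_interaction,
        "reference": cfg.reporter_reference,
        "triple": triple_name,
        "expected_triple_fc": m_a * m_b,
    }
    return groups, truth
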