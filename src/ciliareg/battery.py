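"""Ciliome gene battery: a curated list of cilium effector genes partitioned into
four functional categories.

The battery used throughout this package distinguishes *core* components (IFT
particles, kinesins, dyneins, BBSome subunits and other proteins present in every
cilium), *subtype*-specific genes (channels and receptors restricted to particular
ciliated neuron classes), *broad* ciliated-system genes without a defined core
function, and *male*-specific cilia genes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

CATEGORIES = ("core", "subtype", "broad", "male")

# tolerated spellings in source tables, mapped to canonical labels
_CATEGORY_ALIASES = {
    "core": "core",
    "core components": "core",
    "core component": "core",
    "subtype": "subtype",
    "subtype specific": "subtype",
    "subtype-specific": "subtype",
    "broad": "broad",
    "broad expression": "broad",
    "male": "male",
    "male specific": "male",
}


class BatteryError(ValueError):
    """Malformed battery table (bad category label, conflicting duplicates...)."""


@dataclass(frozen=True)
class BatteryGene:
    """One effector gene of the battery."""

    gene_id: str
    category: str
    public_name: str = ""

    def __post_init__(self):
        if not self.gene_id:
            raise BatteryError("gene_id must be non-empty")
        if self.category not in CATEGORIES:
            raise BatteryError(f"unknown category {self.category!r}")


@dataclass
class GeneBattery:
    """A named collection of BatteryGene with unique gene ids."""

    genes: list[BatteryGene] = field(default_factory=list)
    name: str = "battery"

    def __post_init__(self):
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise BatteryError("duplicate gene ids in battery")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def gene_ids(self) -> set[str]:
        return {g.gene_id for g in self.genes}

    def by_category(self, category: str) -> set[str]:
        if category not in CATEGORIES:
            raise BatteryError(f"unknown category {category!r}")
        return {g.gene_id for g in self.genes if g.category == category}


def normalize_category(label: str) -> str:
    """Canonicalize a category label: lower-case, strip quotes/asterisks/numbering."""
    clean = label.strip().strip("\"'*").lower()
    clean = clean.lstrip("(1234) ").strip("'*‘’ ")
    if clean in _CATEGORY_ALIASES:
        return _CATEGORY_ALIASES[clean]
    raise BatteryError(f"unmappable category label {label!r}")


def load_battery(
    path,
    column_spec: dict | None = None,
    name: str = "battery",
    delimiter: str | None = None,
) -> GeneBattery:
    """Load a battery from a delimited text file with a header row.

    ``column_spec`` maps the roles ``gene_id``, ``category`` and optionally
    ``public_name`` to the column names of the file.  Duplicate gene ids collapse
    to one record only when their categories agree; a conflict raises.
    When the gene-id column is absent from a row the public name is used as the
    identifier (case-insensitive match).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    spec = {"gene_id": "gene_id", "category": "category", "public_name": "public_name"}
    if column_spec:
        spec.update(column_spec)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","

    seen: dict[str, BatteryGene] = {}
    order: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            return GeneBattery([], name=name)
        for col in (spec["gene_id"], spec["category"]):
            if col not in reader.fieldnames and col != spec["gene_id"]:
                raise BatteryError(f"column {col!r} not found in {path.name}")
        for row in reader:
            gid = (row.get(spec["gene_id"]) or "").strip()
            public = (row.get(spec["public_name"]) or "").strip()
            if not gid:
                if not public:
                    raise BatteryError(f"row without gene id or public name: {row}")
                gid = public.lower()
            raw_cat = row.get(spec["category"])
            if raw_cat is None:
                raise BatteryError(f"column {spec['category']!r} not found in {path.name}")
            cat = normalize_category(raw_cat)
            gene = BatteryGene(gene_id=gid, category=cat, public_name=public)
            if gid in seen:
                if seen[gid].category != cat:
                    raise BatteryError(
                        f"duplicate gene {gid!r} with conflicting categories "
                        f"{seen[gid].category!r} vs {cat!r}"
                    )
                continue
            seen[gid] = gene
            order.append(gid)
    return GeneBattery([seen[g] for g in order], name=name)


def write_battery(battery: GeneBattery, path) -> None:
    """Write the canonical two-column TSV (gene_id, category)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["gene_id", "category"])
        for gene in battery:
            writer.writerow([gene.gene_id, gene.category])


def category_counts(battery: GeneBattery) -> dict[str, int]:
    """Per-category gene counts; absent categories are reported as 0."""
    counts = {c: 0 for c in CATEGORIES}
    for gene in battery:
        counts[gene.category] += 1
    return counts
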