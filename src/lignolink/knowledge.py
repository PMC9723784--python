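"""Loaders for compound catalogs, enzyme-substrate maps and gene counts.

All three inputs are UTF-8 tab-delimited tables with a header row and
``#`` comment lines — the least-surprising carrier for hand-curated
tables of the kind assembled from eLignin, KEGG and PMBD:

``compounds``   id, name, smiles, partition (LDCC|PDCC) [, xref]
``enzymes``     id, name, ec, ko, substrates (comma-separated LDCC ids)
``annotation``  genome_id, enzyme_id, gene_count

A packaged fixture (:func:`builtin_fixture`) covers flagship compounds and
beta-ketoadipate-pathway enzymes of lignin-assisted plastic catabolism, so
the whole pipeline runs without any download.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .chem_core import SmilesError, parse_smiles

__all__ = [
    "CompoundRecord",
    "EnzymeRecord",
    "GenomeAnnotation",
    "CatalogError",
    "load_compound_catalog",
    "load_enzyme_map",
    "load_genome_annotation",
    "builtin_fixture",
]

logger = logging.getLogger(__name__)

PARTITIONS = ("LDCC", "PDCC")


class CatalogError(ValueError):
    """Raised for unreadable or inconsistent knowledge tables."""


@dataclass(frozen=True)
class CompoundRecord:
    id: str
    name: str
    smiles: str
    partition: str  # LDCC | PDCC
    xref: str | None = None


@dataclass(frozen=True)
class EnzymeRecord:
    id: str
    name: str
    ec: str | None = None
    ko: tuple[str, ...] = ()
    substrates: tuple[str, ...] = ()  # LDCC compound ids


@dataclass
class GenomeAnnotation:
    """Per-genome gene counts per enzyme; absent pairs count as 0."""

    counts: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def genome_ids(self) -> list[str]:
        return sorted(self.counts)

    def count(self, genome_id: str, enzyme_id: str) -> int:
        row = self.counts.get(genome_id)
        if row is None or enzyme_id not in row:
            logger.warning(
                "no gene count recorded for (%s, %s); defaulting to 0",
                genome_id,
                enzyme_id,
            )
            return 0
        return row[enzyme_id]

    def for_enzyme(self, enzyme_id: str) -> dict[str, int]:
        """Gene count of one enzyme in every annotated genome."""
        return {g: self.counts[g].get(enzyme_id, 0) for g in self.genome_ids}


def _read_tsv(path, required: tuple[str, ...]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    except FileNotFoundError:
        raise CatalogError(f"input file not found: {path}") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CatalogError(f"{path}: missing required column(s) {missing}")
    return df


def load_compound_catalog(
    path, strict: bool = True, largest_component: bool = False
) -> list[CompoundRecord]:
    """Load and SMILES-validate a compound catalog.

    Every row's SMILES must parse under the built-in parser and the
    partition must be LDCC or PDCC.  In strict mode any bad row aborts the
    load with a per-row report; in lenient mode bad rows are dropped with
    warnings.  Duplicate ids are always fatal.
    """
    df = _read_tsv(path, ("id", "name", "smiles", "partition"))
    dupes = df["id"][df["id"].duplicated()].tolist()
    if dupes:
        raise CatalogError(f"{path}: duplicate compound id(s) {sorted(set(dupes))}")

    records: list[CompoundRecord] = []
    errors: list[str] = []
    for _, row in df.iterrows():
        cid = row["id"].strip()
        problem = None
        if row["partition"] not in PARTITIONS:
            problem = f"partition {row['partition']!r} not in {PARTITIONS}"
        else:
            try:
                parse_smiles(row["smiles"], cid, largest_component=largest_component)
            except SmilesError as exc:
                problem = f"bad SMILES {row['smiles']!r}: {exc}"
        if problem:
            errors.append(f"row {cid!r}: {problem}")
            continue
        records.append(
            CompoundRecord(
                id=cid,
                name=row["name"],
                smiles=row["smiles"],
                partition=row["partition"],
                xref=row.get("xref", "") or None,
            )
        )
    if errors:
        if strict:
            raise CatalogError(f"{path}: {len(errors)} invalid row(s): " + "; ".join(errors))
        for e in errors:
            logger.warning("%s: dropped %s", path, e)
    return records


def load_enzyme_map(
    path, compounds: list[CompoundRecord], strict: bool = True
) -> list[EnzymeRecord]:
    """Load the enzyme-substrate map, resolving substrates to LDCC ids.

    Substrate ids that do not resolve to an LDCC compound are reported; an
    enzyme left with zero resolvable substrates is fatal in strict mode and
    dropped with a warning otherwise.
    """
    df = _read_tsv(path, ("id", "name", "ec", "ko", "substrates"))
    dupes = df["id"][df["id"].duplicated()].tolist()
    if dupes:
        raise CatalogError(f"{path}: duplicate enzyme id(s) {sorted(set(dupes))}")
    ldcc_ids = {c.id for c in compounds if c.partition == "LDCC"}
    non_ldcc = {c.id for c in compounds} - ldcc_ids

    records: list[EnzymeRecord] = []
    errors: list[str] = []
    for _, row in df.iterrows():
        eid = row["id"].strip()
        wanted = [s.strip() for s in row["substrates"].split(",") if s.strip()]
        resolved = tuple(s for s in wanted if s in ldcc_ids)
        bad = [s for s in wanted if s not in ldcc_ids]
        for s in bad:
            kind = "a PDCC, not an LDCC" if s in non_ldcc else "unknown"
            errors.append(f"enzyme {eid!r}: substrate {s!r} is {kind}")
        if not resolved:
            errors.append(f"enzyme {eid!r}: zero resolvable LDCC substrates")
            continue
        records.append(
            EnzymeRecord(
                id=eid,
                name=row["name"],
                ec=row["ec"] or None,
                ko=tuple(k.strip() for k in row["ko"].split(",") if k.strip()),
                substrates=resolved,
            )
        )
    if errors:
        if strict:
            raise CatalogError(f"{path}: " + "; ".join(errors))
        for e in errors:
            logger.warning("%s: %s", path, e)
    return records


def load_genome_annotation(path) -> GenomeAnnotation:
    """Load per-genome gene counts; counts must be non-negative integers."""
    df = _read_tsv(path, ("genome_id", "enzyme_id", "gene_count"))
    counts: dict[str, dict[str, int]] = {}
    for _, row in df.iterrows():
        raw = row["gene_count"].strip()
        try:
            n = int(raw)
        except ValueError:
            raise CatalogError(
                f"{path}: non-integer gene_count {raw!r} for "
                f"({row['genome_id']}, {row['enzyme_id']})"
            ) from None
        if n < 0:
            raise CatalogError(
                f"{path}: negative gene_count {n} for "
                f"({row['genome_id']}, {row['enzyme_id']})"
            )
        counts.setdefault(row["genome_id"], {})[row["enzyme_id"]] = n
    return GenomeAnnotation(counts=counts)


def _data_path(filename: str) -> Path:
    return Path(resources.files("lignolink").joinpath("data", filename))  # type: ignore[arg-type]


def builtin_fixture() -> tuple[list[CompoundRecord], list[EnzymeRecord], GenomeAnnotation]:
    """The packaged built-in fixture: compounds, enzymes, gene counts.

    Compounds and enzyme-substrate links cover the flagship molecules of
    lignin-assisted plastic catabolism (monomethyl phthalate, 3,4-dihydroxyphthalate, terephthalic acid and the
    hydroxyalkanoates on the plastic side; the beta-ketoadipate-pathway
    funnels on the lignin side).  The per-genome gene counts are a SYNTHETIC
    illustrative stand-in, not measured annotation counts.
    """
    compounds = load_compound_catalog(_data_path("compounds.tsv"))
    enzymes = load_enzyme_map(_data_path("enzymes.tsv"), compounds)
    annotation = load_genome_annotation(_data_path("genome_counts_synthetic.tsv"))
    return compounds, enzymes, annotation
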