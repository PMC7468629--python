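"""Readers and writers for every external representation the pipeline touches.

The canonical interchange format is a genotype TSV with the header
``sample<TAB>population<TAB><locus_1>...<locus_L>`` and cell values that are
either insertion dosages (``0``/``1``/``2``), two-letter genotypes
(``II``/``ID``/``DD``), or ``./.`` for missing.  Dosage counts copies of the
insertion allele; missing genotypes are stored as :data:`MISSING`.

A VCF importer for biallelic indel records, a STRUCTURE two-row export and
Newick tree IO (via Bio.Phylo) are provided for interoperability.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import Phylo

from .errors import (
    DuplicateSampleIdError,
    RaggedRowError,
    UnknownTokenError,
    UnmappedSampleError,
)

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype in the dosage matrix.
MISSING: int = -1

_TOKEN_TO_DOSAGE = {
    "0": 0, "1": 1, "2": 2,
    "II": 2, "ID": 1, "DI": 1, "DD": 0,
    "./.": MISSING, ".": MISSING, "NA": MISSING,
}


@dataclass
class GenotypeTable:
    """Samples x loci insertion-dosage matrix with population labels.

    Attributes
    ----------
    sample_ids:
        Unique sample identifiers, one per row of ``dosage``.
    population_labels:
        One population label per sample (labels partition the samples).
    locus_ids:
        Unique locus identifiers, one per column of ``dosage``.
    dosage:
        ``(n_samples, n_loci)`` integer array with entries in
        ``{0, 1, 2, MISSING}`` counting insertion alleles.
    """

    sample_ids: list[str]
    population_labels: list[str]
    locus_ids: list[str]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int16)
        n, L = self.dosage.shape
        if len(self.sample_ids) != n or len(self.population_labels) != n:
            raise ValueError("sample_ids/population_labels length mismatch with dosage rows")
        if len(self.locus_ids) != L:
            raise ValueError("locus_ids length mismatch with dosage columns")
        if len(set(self.sample_ids)) != n:
            raise DuplicateSampleIdError("duplicate sample ids in table")
        if len(set(self.locus_ids)) != L:
            raise ValueError("duplicate locus ids in table")
        valid = np.isin(self.dosage, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.unique(self.dosage[~valid])
            raise ValueError(f"dosage entries outside {{0,1,2,{MISSING}}}: {bad}")

    # -- basic queries -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosage.shape[1]

    @property
    def populations(self) -> list[str]:
        """Population labels in first-appearance order."""
        return list(dict.fromkeys(self.population_labels))

    def population_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for lab in self.population_labels:
            sizes[lab] = sizes.get(lab, 0) + 1
        return sizes

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    # -- subsetting ----------------------------------------------------

    def subset_loci(self, locus_ids: Sequence[str] | None = None,
                    exclude: Sequence[str] | None = None) -> "GenotypeTable":
        """Return a table restricted to ``locus_ids`` (or all minus ``exclude``)."""
        if locus_ids is None:
            drop = set(exclude or ())
            keep = [l for l in self.locus_ids if l not in drop]
        else:
            missing = set(locus_ids) - set(self.locus_ids)
            if missing:
                raise KeyError(f"unknown loci: {sorted(missing)}")
            keep = list(locus_ids)
        idx = [self.locus_ids.index(l) for l in keep]
        return GenotypeTable(list(self.sample_ids), list(self.population_labels),
                             keep, self.dosage[:, idx])

    def subset_populations(self, labels: Sequence[str]) -> "GenotypeTable":
        wanted = set(labels)
        rows = [i for i, lab in enumerate(self.population_labels) if lab in wanted]
        return GenotypeTable([self.sample_ids[i] for i in rows],
                             [self.population_labels[i] for i in rows],
                             list(self.locus_ids), self.dosage[rows])

    def genotype_counts(self, pop: str | None = None) -> np.ndarray:
        """Per-locus ``(n_II, n_ID, n_DD)`` counts, optionally within one population.

        Returns an ``(n_loci, 3)`` integer array; missing genotypes are not
        counted anywhere.
        """
        d = self.dosage
        if pop is not None:
            rows = [i for i, lab in enumerate(self.population_labels) if lab == pop]
            d = d[rows]
        out = np.empty((d.shape[1], 3), dtype=np.int64)
        out[:, 0] = (d == 2).sum(axis=0)
        out[:, 1] = (d == 1).sum(axis=0)
        out[:, 2] = (d == 0).sum(axis=0)
        return out

    def insertion_frequencies(self, pop: str | None = None) -> np.ndarray:
        """Per-locus insertion allele frequency from observed alleles only."""
        c = self.genotype_counts(pop)
        denom = 2 * c.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, (2 * c[:, 0] + c[:, 1]) / denom, np.nan)


@dataclass
class LocusSpec:
    """Identity of one biallelic InDel locus."""

    locus_id: str
    insertion_allele_label: str = "I"
    deletion_allele_label: str = "D"
    chrom: str | None = None
    pos: int | None = None  # 1-based, VCF convention

    def __post_init__(self) -> None:
        if self.insertion_allele_label == self.deletion_allele_label:
            raise ValueError("insertion and deletion allele labels must differ")


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    input_path: str | None = None
    output_dir: str = "panel_out"
    include_loci: list[str] | None = None
    exclude_loci: list[str] = field(default_factory=list)
    target_group: str | None = None
    stages: list[str] | None = None  # None = all
    k_range: tuple[int, int] = (2, 5)
    em_restarts: int = 5
    em_max_iter: int = 500
    em_tol: float = 1e-6
    smoothing: float = 0.5
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "input_path": self.input_path,
            "output_dir": self.output_dir,
            "include_loci": self.include_loci,
            "exclude_loci": list(self.exclude_loci),
            "target_group": self.target_group,
            "stages": self.stages,
            "k_range": list(self.k_range),
            "em_restarts": self.em_restarts,
            "em_max_iter": self.em_max_iter,
            "em_tol": self.em_tol,
            "smoothing": self.smoothing,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# genotype TSV
# ---------------------------------------------------------------------------

def read_genotype_table(path: str | Path) -> GenotypeTable:
    """Read the canonical genotype TSV.

    Accepts dosage (``0/1/2``), two-letter (``II/ID/DD``) and ``./.`` cell
    encodings, mixed freely; all are normalized to insertion dosage.

    Raises
    ------
    DuplicateSampleIdError, UnknownTokenError, RaggedRowError
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 3 or header[0] != "sample" or header[1] != "population":
            raise RaggedRowError(
                f"{path}: header must start with 'sample\\tpopulation' followed by loci")
        locus_ids = header[2:]
        sample_ids: list[str] = []
        pops: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise RaggedRowError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}")
            sid, pop = fields[0], fields[1]
            if sid in sample_ids:
                raise DuplicateSampleIdError(f"{path}:{lineno}: duplicate sample id {sid!r}")
            row = []
            for locus, tok in zip(locus_ids, fields[2:]):
                try:
                    row.append(_TOKEN_TO_DOSAGE[tok.strip()])
                except KeyError:
                    raise UnknownTokenError(
                        f"{path}:{lineno}: unknown genotype token {tok!r} at locus {locus}"
                    ) from None
            sample_ids.append(sid)
            pops.append(pop)
            rows.append(row)
    dosage = np.array(rows, dtype=np.int16).reshape(len(rows), len(locus_ids))
    return GenotypeTable(sample_ids, pops, locus_ids, dosage)


def write_genotype_table(table: GenotypeTable, path: str | Path) -> None:
    """Write the canonical genotype TSV (dosage encoding, ``./.`` for missing)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("sample\tpopulation\t" + "\t".join(table.locus_ids) + "\n")
        for i, (sid, pop) in enumerate(zip(table.sample_ids, table.population_labels)):
            cells = ["./." if d == MISSING else str(int(d)) for d in table.dosage[i]]
            fh.write(f"{sid}\t{pop}\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# VCF import
# ---------------------------------------------------------------------------

def read_vcf_biallelic_indels(
    path: str | Path,
    sample_to_population: Mapping[str, str],
    *,
    ignore_unmapped: bool = False,
) -> GenotypeTable:
    """Import biallelic indel records from a VCF into a :class:`GenotypeTable`.

    The insertion allele is the longer of REF/ALT; dosage counts its copies.
    Multiallelic and non-indel records are skipped (count logged).

    Parameters
    ----------
    sample_to_population:
        Maps VCF sample names to population labels.  Samples absent from the
        map raise :class:`UnmappedSampleError` unless ``ignore_unmapped``.
    """
    import pysam

    vf = pysam.VariantFile(str(path))
    vcf_samples = list(vf.header.samples)
    unmapped = [s for s in vcf_samples if s not in sample_to_population]
    if unmapped and not ignore_unmapped:
        raise UnmappedSampleError(f"samples without population mapping: {unmapped[:5]}")
    keep = [s for s in vcf_samples if s in sample_to_population]

    locus_ids: list[str] = []
    columns: list[np.ndarray] = []
    skipped = 0
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            skipped += 1
            continue
        ref, alt = rec.ref, rec.alts[0]
        if len(ref) == len(alt):  # not an indel
            skipped += 1
            continue
        ins_index = 0 if len(ref) > len(alt) else 1
        col = np.full(len(keep), MISSING, dtype=np.int16)
        for j, s in enumerate(keep):
            gt = rec.samples[s].get("GT")
            if gt is None or any(a is None for a in gt):
                continue
            col[j] = sum(1 for a in gt if a == ins_index)
        locus_ids.append(rec.id or f"{rec.chrom}:{rec.pos}")
        columns.append(col)
    vf.close()
    if skipped:
        logger.info("read_vcf_biallelic_indels: skipped %d non-biallelic-indel records", skipped)
    dosage = (np.column_stack(columns) if columns
              else np.empty((len(keep), 0), dtype=np.int16))
    pops = [sample_to_population[s] for s in keep]
    return GenotypeTable(keep, pops, locus_ids, dosage)


# ---------------------------------------------------------------------------
# STRUCTURE export
# ---------------------------------------------------------------------------

def write_structure_file(table: GenotypeTable, path: str | Path) -> None:
    """Write the two-row-per-individual STRUCTURE input format.

    Allele codes: insertion = 1, deletion = 2, missing = -9.  Heterozygotes
    are written insertion-first (order is irrelevant to the likelihood).
    Population labels become 1-based integer codes; the legend goes to
    ``<path>.pops.tsv``.
    """
    path = Path(path)
    pops = list(dict.fromkeys(table.population_labels))
    pop_code = {p: i + 1 for i, p in enumerate(pops)}
    row_alleles = {2: ("1", "1"), 1: ("1", "2"), 0: ("2", "2"), MISSING: ("-9", "-9")}
    with path.open("w") as fh:
        fh.write("\t".join(["", ""] + table.locus_ids) + "\n")
        for i, (sid, pop) in enumerate(zip(table.sample_ids, table.population_labels)):
            first = [row_alleles[int(d)][0] for d in table.dosage[i]]
            second = [row_alleles[int(d)][1] for d in table.dosage[i]]
            fh.write("\t".join([sid, str(pop_code[pop])] + first) + "\n")
            fh.write("\t".join([sid, str(pop_code[pop])] + second) + "\n")
    with Path(str(path) + ".pops.tsv").open("w") as fh:
        fh.write("code\tpopulation\n")
        for p, c in pop_code.items():
            fh.write(f"{c}\t{p}\n")


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def tree_to_newick(tree) -> str:
    """Serialize a Bio.Phylo tree to a Newick string with full-precision lengths."""
    import re

    buf = io.StringIO()
    Phylo.write(tree, buf, "newick", format_branch_length="%.17g")
    s = buf.getvalue().strip()
    return re.sub(r"\):0;$", ");", s)  # drop the spurious zero-length root edge


def write_newick(tree, path: str | Path) -> None:
    """Write a Bio.Phylo tree as Newick (terminated by ``;``)."""
    Path(path).write_text(tree_to_newick(tree) + "\n")


def read_newick(path: str | Path):
    """Parse a Newick file into a Bio.Phylo tree."""
    return Phylo.read(str(path), "newick")
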