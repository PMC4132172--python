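"""Core data model and file formats for the pipeline.

The pipeline consumes per-locus *phased* haplotype alignments (exactly two
haplotype rows per diploid individual), a population metadata table with
geographic coordinates and leaf-shape genotypes, and a minimal coding-region
annotation used to split alignment columns into silent (noncoding or
synonymous) and nonsynonymous classes.  Phasing is an input contract, not a
computation performed here.

Conventions
-----------
* All coordinates are 0-based, half-open; alignment columns index from 0.
* FASTA headers follow ``>INDIVIDUAL|hap1`` / ``>INDIVIDUAL|hap2``.
* Columns containing gaps or IUPAC ambiguity codes are classified
  ``excluded`` and dropped from every statistic.
"""

from __future__ import annotations

import csv
import io as _io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "SITE_EXCLUDED",
    "SITE_NONCODING",
    "SITE_SYNONYMOUS",
    "SITE_NONSYNONYMOUS",
    "HaplotypeAlignment",
    "CodingAnnotation",
    "SnpMatrix",
    "read_haplotype_fasta",
    "write_haplotype_fasta",
    "read_population_table",
    "write_population_table",
    "assign_regions",
    "read_coding_annotation",
    "write_coding_annotation",
    "classify_sites",
    "extract_snps",
    "MalformedInputError",
]

SITE_EXCLUDED = "excluded"
SITE_NONCODING = "silent_noncoding"
SITE_SYNONYMOUS = "synonymous"
SITE_NONSYNONYMOUS = "nonsynonymous"

_VALID_BASES = frozenset("ACGT")
_SILENT_CLASSES = (SITE_NONCODING, SITE_SYNONYMOUS)

POPULATION_COLUMNS = [
    "individual_id",
    "population_id",
    "latitude",
    "longitude",
    "leaf_genotype",
]
LEAF_GENOTYPES = ("LL", "Ll", "ll", "unknown")


class MalformedInputError(ValueError):
    """Raised when an input file violates the documented conventions."""


@dataclass
class HaplotypeAlignment:
    """Per-locus matrix of phased haplotype sequences.

    Parameters
    ----------
    locus_id : str
        Locus label.
    sequences : ndarray of shape (n_haplotypes, length_bp), dtype ``<U1``
        One row per haplotype, upper-case nucleotide characters.
    individuals : list of str
        Individual ID for each haplotype row; every individual must own
        exactly two rows.
    site_classes : ndarray of str, shape (length_bp,)
        Per-column class, one of the ``SITE_*`` constants.  Initialised to
        ``excluded`` by the reader; :func:`classify_sites` fills it in.
    silent_weights : ndarray of float, shape (length_bp,), optional
        Effective silent-site weight per column (noncoding columns count 1,
        CDS columns count their mean fractional degeneracy, excluded
        columns 0).  Set by :func:`classify_sites`.
    """

    locus_id: str
    sequences: np.ndarray
    individuals: list[str]
    site_classes: np.ndarray = None
    silent_weights: np.ndarray | None = None

    def __post_init__(self):
        self.sequences = np.asarray(self.sequences, dtype="<U1")
        if self.sequences.ndim != 2:
            raise MalformedInputError("sequence matrix must be 2-D")
        n, L = self.sequences.shape
        if len(self.individuals) != n:
            raise MalformedInputError(
                "haplotype_to_individual mapping length does not match rows"
            )
        counts = pd.Series(self.individuals).value_counts()
        bad = counts[counts != 2]
        if len(bad):
            raise MalformedInputError(
                f"individual(s) without exactly 2 haplotypes: {sorted(bad.index)}"
            )
        if self.site_classes is None:
            self.site_classes = np.full(L, SITE_EXCLUDED, dtype=object)
        self.site_classes = np.asarray(self.site_classes, dtype=object)
        if self.site_classes.shape != (L,):
            raise MalformedInputError("site_classes length must equal length_bp")

    @property
    def n_haplotypes(self) -> int:
        return self.sequences.shape[0]

    @property
    def length_bp(self) -> int:
        return self.sequences.shape[1]

    def individual_ids(self) -> list[str]:
        """Unique individual IDs in first-appearance order."""
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(ind)
        return list(seen)

    def column_states(self, j: int) -> np.ndarray:
        """Distinct valid (ACGT) states observed in column *j*."""
        col = self.sequences[:, j]
        return np.unique(col[np.isin(col, list(_VALID_BASES))])

    def silent_columns(self) -> np.ndarray:
        """Boolean mask of columns classified silent (noncoding or synonymous)."""
        return np.isin(self.site_classes, _SILENT_CLASSES)

    def subset_individuals(self, keep: list[str]) -> "HaplotypeAlignment":
        keep_set = set(keep)
        rows = [i for i, ind in enumerate(self.individuals) if ind in keep_set]
        return replace(
            self,
            sequences=self.sequences[rows],
            individuals=[self.individuals[i] for i in rows],
            site_classes=self.site_classes.copy(),
            silent_weights=None if self.silent_weights is None else self.silent_weights.copy(),
        )


@dataclass
class CodingAnnotation:
    """CDS intervals for one locus, 0-based half-open, plus reading frame.

    ``frame`` is the offset of the first complete-codon base relative to the
    start of the concatenated CDS.  The concatenated CDS length need not be a
    multiple of three (partial terminal codons are simply not scored).
    """

    locus_id: str
    cds_intervals: list[tuple[int, int]] = field(default_factory=list)
    frame: int = 0

    def __post_init__(self):
        if self.frame not in (0, 1, 2):
            raise MalformedInputError(f"frame must be 0, 1 or 2, got {self.frame}")
        iv = sorted((int(a), int(b)) for a, b in self.cds_intervals)
        for (a, b) in iv:
            if a < 0 or b <= a:
                raise MalformedInputError(f"bad CDS interval ({a}, {b})")
        for (_, b1), (a2, _) in zip(iv, iv[1:]):
            if a2 < b1:
                raise MalformedInputError("CDS intervals overlap")
        self.cds_intervals = iv

    def cds_columns(self) -> np.ndarray:
        """All alignment columns inside a CDS interval, ascending."""
        cols: list[int] = []
        for a, b in self.cds_intervals:
            cols.extend(range(a, b))
        return np.asarray(cols, dtype=int)


@dataclass
class SnpMatrix:
    """Biallelic SNPs as diploid allele-dosage genotypes.

    ``genotypes[i, j]`` counts copies of the *minor* allele of SNP *j*
    carried by individual *i* (0, 1, 2, or -1 for missing).
    """

    snp_ids: list[tuple[str, int]]
    genotypes: np.ndarray  # (n_individuals, n_snps) int8
    allele_labels: list[tuple[str, str]]  # (major, minor) nucleotide states
    individuals: list[str]

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        n, s = self.genotypes.shape
        if len(self.individuals) != n or len(self.snp_ids) != s or len(self.allele_labels) != s:
            raise MalformedInputError("SnpMatrix dimensions inconsistent")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def locus_ids(self) -> np.ndarray:
        return np.asarray([locus for locus, _ in self.snp_ids], dtype=object)

    def subset_snps(self, idx) -> "SnpMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return SnpMatrix(
            snp_ids=[self.snp_ids[i] for i in idx],
            genotypes=self.genotypes[:, idx],
            allele_labels=[self.allele_labels[i] for i in idx],
            individuals=list(self.individuals),
        )

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{locus}:{pos}" for locus, pos in self.snp_ids]
        return pd.DataFrame(self.genotypes, index=self.individuals, columns=cols)


# ---------------------------------------------------------------------------
# FASTA haplotype alignments
# ---------------------------------------------------------------------------

def read_haplotype_fasta(path, metadata: pd.DataFrame | None = None,
                         locus_id: str | None = None) -> HaplotypeAlignment:
    """Read a per-locus phased haplotype alignment.

    Headers must be ``IND_ID|hapN``; the locus ID defaults to the file stem.
    If *metadata* (a population table) is supplied, every individual in the
    FASTA must appear in it.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise MalformedInputError(f"{path}: empty FASTA")
    individuals = []
    rows = []
    lengths = set()
    for rec in records:
        ind = rec.id.split("|", 1)[0]
        individuals.append(ind)
        seq = str(rec.seq).upper()
        lengths.add(len(seq))
        rows.append(list(seq))
    if len(lengths) != 1:
        raise MalformedInputError(
            f"{path}: ragged alignment, sequence lengths {sorted(lengths)}"
        )
    aln = HaplotypeAlignment(
        locus_id=locus_id or path.stem,
        sequences=np.asarray(rows, dtype="<U1"),
        individuals=individuals,
    )
    if metadata is not None:
        known = set(metadata["individual_id"])
        missing = [i for i in aln.individual_ids() if i not in known]
        if missing:
            raise MalformedInputError(
                f"{path}: individuals absent from population table: {missing}"
            )
    return aln


def write_haplotype_fasta(aln: HaplotypeAlignment, path) -> None:
    """Write the alignment back out with the ``IND|hapN`` header convention."""
    hap_counter: dict[str, int] = {}
    records = []
    for ind, row in zip(aln.individuals, aln.sequences):
        hap_counter[ind] = hap_counter.get(ind, 0) + 1
        records.append(
            SeqRecord(Seq("".join(row)), id=f"{ind}|hap{hap_counter[ind]}",
                      description="")
        )
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta-2line")


# ---------------------------------------------------------------------------
# Population metadata
# ---------------------------------------------------------------------------

def read_population_table(path) -> pd.DataFrame:
    """Read the population metadata CSV.

    Required columns: individual_id, population_id, latitude, longitude,
    leaf_genotype (LL/Ll/ll/unknown).  An optional ``region`` column is kept
    if present; otherwise call :func:`assign_regions` with the clinal
    boundary latitude.
    """
    df = pd.read_csv(path, dtype={"individual_id": str, "population_id": str})
    missing = [c for c in POPULATION_COLUMNS if c not in df.columns]
    if missing:
        raise MalformedInputError(f"population table missing columns {missing}")
    if df["individual_id"].duplicated().any():
        dups = df.loc[df["individual_id"].duplicated(), "individual_id"].tolist()
        raise MalformedInputError(f"duplicate individual IDs: {dups}")
    df["leaf_genotype"] = df["leaf_genotype"].fillna("unknown")
    bad = set(df["leaf_genotype"]) - set(LEAF_GENOTYPES)
    if bad:
        raise MalformedInputError(f"unrecognized leaf genotypes: {sorted(bad)}")
    return df


def write_population_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def assign_regions(meta: pd.DataFrame, boundary_latitude: float) -> pd.DataFrame:
    """Label each individual ``north``/``south`` of the clinal boundary.

    The boundary is a configured constant imported from prior work on the
    leaf-shape cline, never estimated here.
    """
    out = meta.copy()
    out["region"] = np.where(out["latitude"] >= boundary_latitude, "north", "south")
    return out


# ---------------------------------------------------------------------------
# Coding annotation (BED-like: locus  start  end  frame)
# ---------------------------------------------------------------------------

def read_coding_annotation(path) -> dict[str, CodingAnnotation]:
    """Read a BED-like file with columns locus, start, end, frame.

    All rows for one locus share the locus-level frame (the frame on the
    first row wins); returns a dict keyed by locus ID.
    """
    per_locus: dict[str, dict] = {}
    with open(path, newline="") as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise MalformedInputError(f"annotation line needs 4 fields: {line!r}")
            locus, start, end, frame = parts[0], int(parts[1]), int(parts[2]), int(parts[3])
            entry = per_locus.setdefault(locus, {"intervals": [], "frame": frame})
            entry["intervals"].append((start, end))
    return {
        locus: CodingAnnotation(locus_id=locus, cds_intervals=d["intervals"],
                                frame=d["frame"])
        for locus, d in per_locus.items()
    }


def write_coding_annotation(annotations: dict[str, CodingAnnotation], path) -> None:
    with open(path, "w") as fh:
        for locus in sorted(annotations):
            ann = annotations[locus]
            for a, b in ann.cds_intervals:
                fh.write(f"{locus}\t{a}\t{b}\t{ann.frame}\n")


# ---------------------------------------------------------------------------
# Site classification
# ---------------------------------------------------------------------------

from functools import lru_cache


@lru_cache(maxsize=256)
def _codon_syn_fraction(codon: str, pos_in_codon: int) -> float:
    """Fraction of the three possible point mutations at this codon position
    that are synonymous (Nei–Gojobori fractional silent-site counting)."""
    table = standard_dna_table.forward_table
    stops = set(standard_dna_table.stop_codons)

    def aa(c):
        if c in stops:
            return "*"
        return table.get(c)

    ref_aa = aa(codon)
    if ref_aa is None:
        return 0.0
    syn = 0
    for alt in "ACGT":
        if alt == codon[pos_in_codon]:
            continue
        mut = codon[:pos_in_codon] + alt + codon[pos_in_codon + 1:]
        if aa(mut) == ref_aa:
            syn += 1
    return syn / 3.0


def classify_sites(aln: HaplotypeAlignment, ann: CodingAnnotation | None) -> HaplotypeAlignment:
    """Classify every column and compute effective silent-site weights.

    Columns outside every CDS interval are ``silent_noncoding`` (weight 1).
    CDS columns are ``synonymous`` when every observed segregating change
    preserves the encoded amino acid in all haplotype codon contexts, else
    ``nonsynonymous``; monomorphic CDS columns take the class of the majority
    of hypothetical point mutations (fourfold-degenerate sites count as
    synonymous).  Either way a CDS column's *weight* is its mean fractional
    degeneracy across haplotypes.  Columns with gaps/ambiguities (or in
    incomplete terminal codons) are ``excluded`` with weight 0.
    """
    if ann is not None and ann.locus_id != aln.locus_id:
        raise MalformedInputError(
            f"annotation locus {ann.locus_id!r} does not match alignment {aln.locus_id!r}"
        )
    n, L = aln.sequences.shape
    classes = np.full(L, SITE_NONCODING, dtype=object)
    weights = np.ones(L, dtype=float)

    valid_col = np.all(np.isin(aln.sequences, list(_VALID_BASES)), axis=0)
    classes[~valid_col] = SITE_EXCLUDED
    weights[~valid_col] = 0.0

    if ann is None or not ann.cds_intervals:
        out = replace(aln)
        out.site_classes = classes
        out.silent_weights = weights
        return out

    cds_cols = ann.cds_columns()
    if len(cds_cols) and cds_cols[-1] >= L:
        raise MalformedInputError(
            f"{aln.locus_id}: CDS interval extends past alignment end ({cds_cols[-1]} >= {L})"
        )

    # Concatenated CDS per haplotype; codons start at `frame` in that
    # concatenation, trailing partial codons are not scored.
    cds_seqs = aln.sequences[:, cds_cols]
    n_cds = len(cds_cols)
    first = ann.frame
    n_codons = (n_cds - first) // 3

    in_codon = np.zeros(n_cds, dtype=bool)
    in_codon[first:first + 3 * n_codons] = True
    # CDS columns not in a complete codon cannot be scored: excluded.
    for k in np.flatnonzero(~in_codon):
        col = cds_cols[k]
        if valid_col[col]:
            classes[col] = SITE_EXCLUDED
            weights[col] = 0.0

    for c in range(n_codons):
        k0 = first + 3 * c
        cols3 = cds_cols[k0:k0 + 3]
        codon_ok = valid_col[cols3].all()
        if codon_ok:
            joined = np.char.add(
                np.char.add(cds_seqs[:, k0], cds_seqs[:, k0 + 1]),
                cds_seqs[:, k0 + 2],
            )
            uniq, counts = np.unique(joined, return_counts=True)
        for off in range(3):
            col = cols3[off]
            if not valid_col[col]:
                continue
            if not codon_ok:
                # degeneracy cannot be evaluated without the full codon
                classes[col] = SITE_EXCLUDED
                weights[col] = 0.0
                continue
            weights[col] = float(
                sum(cnt * _codon_syn_fraction(str(cd), off)
                    for cd, cnt in zip(uniq, counts)) / n
            )
            states = np.unique(aln.sequences[:, col])
            if len(states) > 1:
                # synonymous iff every observed change is silent in every
                # observed codon context
                table = standard_dna_table.forward_table
                stops = set(standard_dna_table.stop_codons)

                def aa(cd):
                    return "*" if cd in stops else table.get(cd, "X")

                synonymous = True
                for cd in map(str, uniq):
                    aas = set()
                    for st in states:
                        mut = cd[:off] + st + cd[off + 1:]
                        aas.add(aa(mut))
                    if len(aas) > 1:
                        synonymous = False
                        break
                classes[col] = SITE_SYNONYMOUS if synonymous else SITE_NONSYNONYMOUS
            else:
                classes[col] = (
                    SITE_SYNONYMOUS if weights[col] >= 0.5 else SITE_NONSYNONYMOUS
                )

    out = replace(aln)
    out.site_classes = classes
    out.silent_weights = weights
    return out


# ---------------------------------------------------------------------------
# SNP extraction
# ---------------------------------------------------------------------------

def extract_snps(alns: list[HaplotypeAlignment], meta: pd.DataFrame) -> SnpMatrix:
    """Collect every biallelic segregating column across loci as dosage genotypes.

    Columns with more than two valid states are dropped (configurable policy
    lives in the diversity module's segregating-site counting, not here).
    Dosage counts the globally minor allele; ties break alphabetically.
    """
    if not alns:
        raise MalformedInputError("no alignments supplied")
    individuals = list(meta["individual_id"])
    snp_ids, allele_labels, columns = [], [], []
    for aln in alns:
        row_of = {}
        for i, ind in enumerate(aln.individuals):
            row_of.setdefault(ind, []).append(i)
        for j in range(aln.length_bp):
            if aln.site_classes[j] == SITE_EXCLUDED and not np.all(
                np.isin(aln.sequences[:, j], list(_VALID_BASES))
            ):
                continue
            states, counts = np.unique(aln.sequences[:, j], return_counts=True)
            ok = np.isin(states, list(_VALID_BASES))
            states, counts = states[ok], counts[ok]
            if len(states) != 2:
                continue
            order = np.lexsort((states, counts))  # minor last? counts asc
            minor, major = states[order[0]], states[order[1]]
            dosage = np.full(len(individuals), -1, dtype=np.int8)
            for i_ind, ind in enumerate(individuals):
                rows = row_of.get(ind)
                if rows is None:
                    continue
                dosage[i_ind] = int(np.sum(aln.sequences[rows, j] == minor))
            snp_ids.append((aln.locus_id, j))
            allele_labels.append((str(major), str(minor)))
            columns.append(dosage)
    genotypes = (
        np.stack(columns, axis=1) if columns else np.zeros((len(individuals), 0), np.int8)
    )
    return SnpMatrix(snp_ids=snp_ids, genotypes=genotypes,
                     allele_labels=allele_labels, individuals=individuals)
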