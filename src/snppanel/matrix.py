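"""Genotype matrix container and I/O.

Dosages count copies of the alternate allele: 0 (homozygous reference),
1 (heterozygous), 2 (homozygous alternate). Missing calls use the sentinel
:data:`MISSING` (-1), never 0, so every downstream statistic must state its
missing-data policy explicitly. Encoding is strand-agnostic: no allele
complementation is ever applied.

Coordinates are 1-based in files (VCF convention) and converted to 0-based
half-open only inside windowing code.
"""

from __future__ import annotations

import enum
import gzip
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np

from .errors import FormatError, UnknownIdError

MISSING: int = -1

_LEGAL_CALLS = (-1, 0, 1, 2)


class Source(str, enum.Enum):
    """Provenance tag for a candidate marker.

    The six named sources mirror the candidate pools a multi-source array
    design draws from: an existing high-density array, a mid-density bead
    chip, transcriptome-derived markers chosen for population
    differentiation, markers from the dispensable (non-reference) genome,
    markers inside well-characterised genes, and tags for transgenic events.
    """

    ARRAY600K = "array600k"
    BEADCHIP50K = "beadchip50k"
    RNASEQ_FST = "rnaseq_fst"
    DISPENSABLE = "dispensable"
    KNOWN_GENE = "known_gene"
    TRANSGENIC_TAG = "transgenic_tag"
    OTHER = "other"


class Population(str, enum.Enum):
    TEMPERATE = "temperate"
    TROPICAL = "tropical"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic SNP: id, physical position and alleles.

    ``pos`` is 1-based. ``ref_allele``/``alt_allele`` are single bases and
    must differ.
    """

    id: str
    chrom: str
    pos: int
    ref_allele: str = "A"
    alt_allele: str = "G"
    source: Source = Source.OTHER

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"variant {self.id}: pos must be >= 1, got {self.pos}")
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise FormatError(
                f"variant {self.id}: alleles must be single bases "
                f"({self.ref_allele!r}/{self.alt_allele!r})"
            )
        if self.ref_allele == self.alt_allele:
            raise FormatError(f"variant {self.id}: ref and alt alleles are identical")


@dataclass(frozen=True)
class SampleRecord:
    id: str
    population: Population = Population.UNKNOWN
    group: str | None = None


@dataclass
class GenotypeMatrix:
    """samples x variants table of dosage calls with metadata.

    Variants are kept sorted by (chrom, pos); the constructor reorders
    columns if needed. ``calls`` is an int8 array of shape
    (n_samples, n_variants) over {-1, 0, 1, 2}.
    """

    variants: list[VariantRecord]
    samples: list[SampleRecord]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2 or self.calls.shape != (len(self.samples), len(self.variants)):
            raise FormatError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        bad = ~np.isin(self.calls, _LEGAL_CALLS)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"illegal call {int(self.calls[i, j])} at sample "
                f"{self.samples[i].id!r}, variant {self.variants[j].id!r}"
            )
        vids = [v.id for v in self.variants]
        if len(set(vids)) != len(vids):
            raise FormatError("duplicate variant ids")
        sids = [s.id for s in self.samples]
        if len(set(sids)) != len(sids):
            raise FormatError("duplicate sample ids")
        order = sorted(range(len(self.variants)), key=lambda j: (self.variants[j].chrom, self.variants[j].pos))
        if order != list(range(len(self.variants))):
            self.variants = [self.variants[j] for j in order]
            self.calls = self.calls[:, order]

    # -- basic accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    @property
    def sample_ids(self) -> list[str]:
        return [s.id for s in self.samples]

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants], dtype=np.int64)

    @property
    def chroms(self) -> np.ndarray:
        return np.array([v.chrom for v in self.variants], dtype=object)

    def chrom_lengths(self) -> dict[str, int]:
        """Observed per-chromosome extent (max position)."""
        out: dict[str, int] = {}
        for v in self.variants:
            out[v.chrom] = max(out.get(v.chrom, 0), v.pos)
        return out

    def variant_indices(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {v.id: j for j, v in enumerate(self.variants)}
        wanted = list(ids)
        unknown = [i for i in wanted if i not in lookup]
        if unknown:
            raise UnknownIdError(f"unknown variant ids: {sorted(unknown)[:10]}")
        return np.array(sorted(lookup[i] for i in wanted), dtype=np.intp)

    def sample_indices(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {s.id: i for i, s in enumerate(self.samples)}
        wanted = list(ids)
        unknown = [i for i in wanted if i not in lookup]
        if unknown:
            raise UnknownIdError(f"unknown sample ids: {sorted(unknown)[:10]}")
        return np.array(sorted(lookup[i] for i in wanted), dtype=np.intp)

    def population_groups(self) -> dict[str, np.ndarray]:
        """Sample indices per declared population (unknown excluded)."""
        out: dict[str, list[int]] = {}
        for i, s in enumerate(self.samples):
            if s.population is not Population.UNKNOWN:
                out.setdefault(s.population.value, []).append(i)
        return {k: np.array(v, dtype=np.intp) for k, v in out.items()}

    def subset(
        self,
        variant_ids: Iterable[str] | None = None,
        sample_ids: Iterable[str] | None = None,
    ) -> "GenotypeMatrix":
        """Subset by id, preserving this matrix's row/column order."""
        vj = self.variant_indices(variant_ids) if variant_ids is not None else np.arange(self.n_variants)
        si = self.sample_indices(sample_ids) if sample_ids is not None else np.arange(self.n_samples)
        return GenotypeMatrix(
            variants=[self.variants[j] for j in vj],
            samples=[self.samples[i] for i in si],
            calls=self.calls[np.ix_(si, vj)].copy(),
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.variants == other.variants
            and self.samples == other.samples
            and np.array_equal(self.calls, other.calls)
        )


# -- VCF ----------------------------------------------------------------


def _opener(path: str | Path, mode: str) -> IO:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t") if "b" not in mode else gzip.open(path, mode)
    return open(path, mode)


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a VCF (v4.x, diploid GT) into a :class:`GenotypeMatrix`.

    Only biallelic single-base SNP records are kept; multi-allelic or
    indel records are dropped with a single :class:`UserWarning` carrying
    the exclusion count. ``./.`` (or ``.|.``) becomes :data:`MISSING`.
    A ``SRC=`` INFO field, when present, populates the source tag.
    """
    import cyvcf2

    path = str(path)
    try:
        vcf = cyvcf2.VCF(path)
        sample_names = list(vcf.samples)
    except Exception as exc:  # cyvcf2 raises bare Exceptions on bad headers
        raise FormatError(f"{path}: malformed VCF header ({exc})") from exc
    header_lines = vcf.raw_header.count("\n")

    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    excluded = 0
    for rec_index, rec in enumerate(vcf):
        line_no = header_lines + rec_index + 1
        alts = rec.ALT
        if len(alts) != 1 or len(rec.REF) != 1 or len(alts[0]) != 1:
            excluded += 1
            continue
        gts = rec.genotypes  # [[a0, a1, phased], ...]
        col = np.empty(len(sample_names), dtype=np.int8)
        for i, gt in enumerate(gts):
            if len(gt) != 3:  # ploidy != 2 (cyvcf2 appends the phase flag)
                raise FormatError(f"{path}: non-diploid GT at line {line_no}, sample {sample_names[i]!r}")
            a0, a1 = gt[0], gt[1]
            col[i] = MISSING if (a0 < 0 or a1 < 0) else a0 + a1
        src = rec.INFO.get("SRC")
        variants.append(
            VariantRecord(
                id=rec.ID or f"{rec.CHROM}_{rec.POS}",
                chrom=rec.CHROM,
                pos=rec.POS,
                ref_allele=rec.REF,
                alt_allele=alts[0],
                source=Source(src) if src else Source.OTHER,
            )
        )
        columns.append(col)
    if excluded:
        warnings.warn(f"{path}: excluded {excluded} non-biallelic/non-SNP record(s)")
    calls = (
        np.stack(columns, axis=1)
        if columns
        else np.zeros((len(sample_names), 0), dtype=np.int8)
    )
    samples = [SampleRecord(id=s) for s in sample_names]
    return GenotypeMatrix(variants=variants, samples=samples, calls=calls)


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF v4.2 (GT only; source tag in INFO ``SRC``)."""
    with _opener(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=snppanel\n")
        fh.write('##INFO=<ID=SRC,Number=1,Type=String,Description="Candidate source pool">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(v.chrom for v in matrix.variants):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(matrix.sample_ids) + "\n")
        for j, v in enumerate(matrix.variants):
            gts = "\t".join(_GT_STRINGS[int(c)] for c in matrix.calls[:, j])
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref_allele}\t{v.alt_allele}"
                f"\t.\t.\tSRC={v.source.value}\tGT\t{gts}\n"
            )


# -- dosage TSV ----------------------------------------------------------

# Dialect: optional "##variant<TAB>id<TAB>chrom<TAB>pos<TAB>ref<TAB>alt<TAB>source"
# lines (one per variant, making the round trip lossless), then a header row
# "sample_id<TAB>population<TAB>group<TAB><variant ids...>", then one row per
# sample with cells in {0,1,2,NA}. Files without ##variant lines are accepted;
# chrom/pos are then synthesized (single pseudo-chromosome, 1-based rank).


def write_matrix_tsv(matrix: GenotypeMatrix, path: str | Path) -> None:
    with _opener(path, "w") as fh:
        for v in matrix.variants:
            fh.write(
                f"##variant\t{v.id}\t{v.chrom}\t{v.pos}\t{v.ref_allele}\t{v.alt_allele}\t{v.source.value}\n"
            )
        fh.write("sample_id\tpopulation\tgroup\t" + "\t".join(matrix.variant_ids) + "\n")
        for i, s in enumerate(matrix.samples):
            cells = "\t".join("NA" if c == MISSING else str(int(c)) for c in matrix.calls[i])
            fh.write(f"{s.id}\t{s.population.value}\t{s.group or '.'}\t{cells}\n")


def read_matrix_tsv(path: str | Path) -> GenotypeMatrix:
    meta: dict[str, VariantRecord] = {}
    with _opener(path, "r") as fh:
        lines = fh.read().splitlines()
    body_start = 0
    for line in lines:
        if not line.startswith("##"):
            break
        body_start += 1
        parts = line.split("\t")
        if parts[0] == "##variant":
            if len(parts) != 7:
                raise FormatError(f"{path}: malformed ##variant line: {line!r}")
            _, vid, chrom, pos, ref, alt, src = parts
            meta[vid] = VariantRecord(vid, chrom, int(pos), ref, alt, Source(src))
    if body_start >= len(lines):
        raise FormatError(f"{path}: missing header row")
    header = lines[body_start].split("\t")
    if header[:2] != ["sample_id", "population"]:
        raise FormatError(f"{path}: header must start with sample_id, population")
    has_group = len(header) > 2 and header[2] == "group"
    first_vcol = 3 if has_group else 2
    vids = header[first_vcol:]
    variants = []
    for rank, vid in enumerate(vids, start=1):
        variants.append(meta.get(vid) or VariantRecord(vid, "0", rank))

    samples: list[SampleRecord] = []
    rows: list[np.ndarray] = []
    for row_index, line in enumerate(lines[body_start + 1 :]):
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != len(header):
            raise FormatError(
                f"{path}: row {row_index} has {len(parts)} fields, expected {len(header)}"
            )
        group = parts[2] if has_group else "."
        samples.append(
            SampleRecord(
                id=parts[0],
                population=Population(parts[1]),
                group=None if group in (".", "") else group,
            )
        )
        row = np.empty(len(vids), dtype=np.int8)
        for j, cell in enumerate(parts[first_vcol:]):
            if cell == "NA":
                row[j] = MISSING
            elif cell in ("0", "1", "2"):
                row[j] = int(cell)
            else:
                raise FormatError(f"{path}: row {row_index}: illegal cell {cell!r}")
        rows.append(row)
    calls = np.stack(rows) if rows else np.zeros((0, len(vids)), dtype=np.int8)
    return GenotypeMatrix(variants=variants, samples=samples, calls=calls)
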