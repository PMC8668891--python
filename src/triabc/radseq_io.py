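"""Reading, writing and filtering observed multi-locus RAD data.

The FASTA dialect carries one record per allele per individual per locus,
with headers ``>species|individual|locus|allele`` (configurable delimiter).
Loci are unanchored: SNP positions are locus-internal and 0-based.  The VCF
dialect stores the same SNPs (CHROM = locus id) with phased diploid
genotypes; a tab-separated locus table (id, length, SNP count, per-species
sample counts) carries the locus lengths that a VCF cannot.

Internally a :class:`LocusDataset` keeps, per locus, only the variable
columns (as bases) plus the locus length; converting to 0/1 SNP matrices
polarizes each site either by the majority allele of the pooled sample
(``"major"``, the only option for real data, where no outgroup is
available — an approximation) or by the lexicographically smaller allele
(``"lex"``, which round-trips simulated data exactly since simulated
ancestral states are written as ``A`` and derived as ``C``).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .coalsim import SimulatedLocus
from .model_space import ConfigurationError, SpeciesTrio

__all__ = [
    "LocusAlignment",
    "LocusDataset",
    "FilterLog",
    "read_loci_fasta",
    "write_loci_fasta",
    "read_vcf",
    "write_vcf",
    "filter_loci",
    "to_snp_matrices",
    "dataset_from_simulated",
    "write_locus_table",
    "read_locus_table",
]

ANCESTRAL_BASE = "A"
DERIVED_BASE = "C"


class ParseError(ValueError):
    """Malformed input file."""


class DataError(ValueError):
    """Structurally valid input that violates the dataset contract."""


@dataclass
class LocusAlignment:
    """Variable columns of one locus across all its sequences."""

    locus_id: str
    length_bp: int
    #: (species, individual, allele index) per row
    names: list[tuple[str, str, int]]
    positions: np.ndarray  # 0-based, sorted
    bases: np.ndarray  # (n_rows, n_sites) of single characters

    def n_alleles_per_site(self) -> list[int]:
        return [len(set(self.bases[:, j])) for j in range(self.bases.shape[1])]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, LocusAlignment)
            and self.locus_id == other.locus_id
            and self.length_bp == other.length_bp
            and self.names == other.names
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.bases, other.bases)
        )


@dataclass
class LocusDataset:
    """A set of loci with species assignments."""

    loci: list[LocusAlignment]
    species_order: tuple[str, ...]

    @property
    def samples(self) -> list[tuple[str, str]]:
        """All (species, individual) pairs seen anywhere in the dataset."""
        seen = dict.fromkeys(
            (sp, ind) for loc in self.loci for sp, ind, _ in loc.names
        )
        return list(seen)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, LocusDataset)
            and self.species_order == other.species_order
            and self.loci == other.loci
        )


@dataclass
class FilterLog:
    """Counts of loci dropped per filtering rule."""

    dropped_missing_sample: int = 0
    dropped_monomorphic: int = 0
    dropped_non_biallelic: int = 0
    sites_dropped_missing: int = 0
    retained: int = 0


def _parse_header(header: str, delimiter: str) -> tuple[str, str, str, int]:
    parts = header.split(delimiter)
    if len(parts) != 4:
        raise ParseError(
            f"header {header!r} does not match "
            f"'species{delimiter}individual{delimiter}locus{delimiter}allele'"
        )
    sp, ind, locus, allele = parts
    try:
        return sp, ind, locus, int(allele)
    except ValueError as exc:
        raise ParseError(f"non-integer allele index in header {header!r}") from exc


def read_loci_fasta(
    path, species_order: tuple[str, ...] | None = None, delimiter: str = "|"
) -> LocusDataset:
    """Parse the multi-locus FASTA dialect into an (unfiltered) dataset.

    Sites containing missing or ambiguous bases (anything outside ACGT)
    are dropped locus-wide; only variable columns are retained in memory.
    """
    groups: dict[str, list[tuple[tuple[str, str, int], str]]] = {}
    n_records = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n_records += 1
        sp, ind, locus, allele = _parse_header(rec.id, delimiter)
        groups.setdefault(locus, []).append(((sp, ind, allele), str(rec.seq).upper()))
    if n_records == 0:
        raise ParseError(f"no FASTA records found in {path}")

    loci = []
    species_seen: dict[str, None] = {}
    for locus_id, rows in groups.items():
        rows.sort(key=lambda r: r[0])
        lengths = {len(seq) for _, seq in rows}
        if len(lengths) != 1:
            raise DataError(
                f"locus {locus_id!r} has sequences of unequal length {sorted(lengths)}"
            )
        length = lengths.pop()
        mat = np.array([list(seq) for _, seq in rows])
        ok = np.isin(mat, list("ACGT")).all(axis=0)
        variable = ok & (np.ptp(mat.view(np.uint32), axis=0) > 0)
        positions = np.flatnonzero(variable)
        names = [name for name, _ in rows]
        for sp, _, _ in names:
            species_seen.setdefault(sp)
        loci.append(LocusAlignment(
            locus_id=locus_id, length_bp=length, names=names,
            positions=positions, bases=mat[:, variable],
        ))
    loci.sort(key=lambda loc: loc.locus_id)
    order = species_order or tuple(sorted(species_seen))
    return LocusDataset(loci=loci, species_order=order)


def _full_sequences(loc: LocusAlignment) -> list[str]:
    background = np.full(loc.length_bp, ANCESTRAL_BASE, dtype="<U1")
    out = []
    for i in range(len(loc.names)):
        seq = background.copy()
        seq[loc.positions] = loc.bases[i]
        out.append("".join(seq))
    return out


def write_loci_fasta(dataset: LocusDataset, path, delimiter: str = "|") -> None:
    """Write the dataset in the multi-locus FASTA dialect.

    Invariant columns are emitted as the ancestral background base.
    """
    records = []
    for loc in dataset.loci:
        for (sp, ind, allele), seq in zip(loc.names, _full_sequences(loc)):
            header = delimiter.join([sp, ind, loc.locus_id, str(allele)])
            records.append(SeqRecord(Seq(seq), id=header, description=""))
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta-2line")


def dataset_from_simulated(
    loci: list[SimulatedLocus], trio: SpeciesTrio
) -> LocusDataset:
    """Wrap simulated SNP matrices as a dataset (ancestral=A, derived=C).

    Consecutive sequence pairs within a population form one diploid
    individual, named ``<species>_<k>``.
    """
    out = []
    base_map = np.array([ANCESTRAL_BASE, DERIVED_BASE])
    for idx, loc in enumerate(loci):
        locus_id = loc.locus_id or f"locus_{idx:05d}"
        names = []
        for pop, label, n in zip((0, 1, 2), trio.labels, trio.n_seq):
            for k in range(n):
                names.append((label, f"{label}_{k // 2:03d}", k % 2 + 1))
        bases = base_map[loc.genotypes]
        # canonical row order (lexicographic), as the readers produce
        order = sorted(range(len(names)), key=lambda i: names[i])
        out.append(LocusAlignment(
            locus_id=locus_id, length_bp=loc.length_bp,
            names=[names[i] for i in order],
            positions=np.asarray(loc.positions), bases=bases[order],
        ))
    return LocusDataset(loci=out, species_order=trio.labels)


def to_snp_matrices(
    dataset: LocusDataset,
    polarization: str = "major",
) -> list[SimulatedLocus]:
    """Convert a (filtered, biallelic) dataset to 0/1 SNP matrices.

    Rows are grouped by species in ``species_order`` and sorted by
    (individual, allele) within species.  ``polarization`` chooses the
    0-allele per site: ``"major"`` (pooled majority, ties broken towards
    the lexicographically smaller base) or ``"lex"`` (smaller base).
    """
    if polarization not in ("major", "lex"):
        raise ValueError(f"unknown polarization {polarization!r}")
    sp_index = {sp: i for i, sp in enumerate(dataset.species_order)}
    out = []
    for loc in dataset.loci:
        order = sorted(
            range(len(loc.names)),
            key=lambda i: (sp_index[loc.names[i][0]], loc.names[i][1],
                           loc.names[i][2]),
        )
        bases = loc.bases[order]
        pops = np.array([sp_index[loc.names[i][0]] for i in order])
        geno = np.zeros_like(bases, dtype=np.int8)
        for j in range(bases.shape[1]):
            col = bases[:, j]
            alleles, counts = np.unique(col, return_counts=True)
            if len(alleles) != 2:
                raise DataError(
                    f"locus {loc.locus_id!r} site {j} is not biallelic; "
                    "run filter_loci first"
                )
            if polarization == "lex" or counts[0] == counts[1]:
                ancestral = min(alleles)
            else:
                ancestral = alleles[np.argmax(counts)]
            geno[:, j] = (col != ancestral).astype(np.int8)
        out.append(SimulatedLocus(
            genotypes=geno, pops=pops, length_bp=loc.length_bp,
            positions=np.asarray(loc.positions), locus_id=loc.locus_id,
        ))
    return out


def filter_loci(dataset: LocusDataset) -> tuple[LocusDataset, FilterLog]:
    """Apply the shared-by-all / polymorphic / biallelic locus filters.

    Retains loci that are (i) present (both alleles) in every sample of the
    dataset, (ii) polymorphic in the pooled alignment and (iii) composed
    exclusively of biallelic SNPs.  Returns the filtered dataset and a log
    of drop counts.  The operation is idempotent.
    """
    log = FilterLog()
    all_samples = set(dataset.samples)
    kept = []
    for loc in dataset.loci:
        present: dict[tuple[str, str], set[int]] = {}
        for sp, ind, al in loc.names:
            present.setdefault((sp, ind), set()).add(al)
        if set(present) != all_samples or any(len(v) < 2 for v in present.values()):
            log.dropped_missing_sample += 1
            continue
        if loc.bases.shape[1] == 0:
            log.dropped_monomorphic += 1
            continue
        if any(k != 2 for k in loc.n_alleles_per_site()):
            log.dropped_non_biallelic += 1
            continue
        kept.append(loc)
    log.retained = len(kept)
    return LocusDataset(loci=kept, species_order=dataset.species_order), log


# ---------------------------------------------------------------------------
# VCF dialect

def _individuals(dataset: LocusDataset) -> list[tuple[str, str]]:
    return dataset.samples


def write_vcf(dataset: LocusDataset, path) -> None:
    """Write the dataset's SNPs as a phased multi-sample VCF (v4.2).

    Sample columns are individuals named ``<species>_<id>``; locus lengths
    are not representable in VCF and travel in the locus table instead.
    """
    individuals = _individuals(dataset)
    ids = [ind for _, ind in individuals]
    lines = ["##fileformat=VCFv4.2",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    for loc in dataset.loci:
        lines.append(f"##contig=<ID={loc.locus_id},length={loc.length_bp}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(ids))
    for loc in dataset.loci:
        row_of = {(sp, ind, al): i for i, (sp, ind, al) in enumerate(loc.names)}
        for j, pos in enumerate(loc.positions):
            col = loc.bases[:, j]
            alleles = sorted(set(col))
            ref, alts = alleles[0], alleles[1:]
            index = {a: k for k, a in enumerate(alleles)}
            gts = []
            for sp, ind in individuals:
                a1 = row_of.get((sp, ind, 1))
                a2 = row_of.get((sp, ind, 2))
                if a1 is None or a2 is None:
                    gts.append(".|.")
                else:
                    gts.append(f"{index[col[a1]]}|{index[col[a2]]}")
            lines.append("\t".join([
                loc.locus_id, str(int(pos) + 1), ".", ref,
                ",".join(alts) or ".", ".", "PASS", ".", "GT", *gts,
            ]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(
    path,
    sample_species: dict[str, str],
    locus_lengths: dict[str, int] | None = None,
    species_order: tuple[str, ...] | None = None,
    rng: np.random.Generator | int | None = None,
) -> LocusDataset:
    """Parse a VCF into an (unfiltered) dataset.

    ``sample_species`` maps VCF sample names to species labels; a sample
    absent from the map is a configuration error.  Unphased heterozygotes
    are phased randomly under ``rng`` (all downstream statistics are
    allele-frequency functions, so phase only affects serialization).
    Sites with missing genotypes are dropped locus-wide; multi-allelic
    sites are kept and flagged by :func:`filter_loci`.  Locus lengths come
    from ``locus_lengths`` (see :func:`read_locus_table`) or default to
    the largest SNP position of the locus.
    """
    from cyvcf2 import VCF

    rng = np.random.default_rng(rng)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for s in samples:
        if s not in sample_species:
            raise ConfigurationError(f"sample {s!r} missing from species map")

    per_locus: dict[str, list[tuple[int, list[str]]]] = {}
    for var in vcf:
        alleles = [var.REF] + list(var.ALT)
        col: list[str] | None = []
        for g in var.genotypes:
            a1, a2, phased = g[0], g[1], bool(g[2])
            if a1 < 0 or a2 < 0:
                col = None  # missing genotype: drop the site
                break
            if not phased and a1 != a2 and rng.random() < 0.5:
                a1, a2 = a2, a1
            col.extend([alleles[a1], alleles[a2]])
        if col is not None:
            per_locus.setdefault(var.CHROM, []).append((var.POS - 1, col))

    loci = []
    species_seen: dict[str, None] = {}
    for locus_id, sites in sorted(per_locus.items()):
        sites.sort(key=lambda s: s[0])
        positions = np.array([p for p, _ in sites], dtype=int)
        names = []
        for s in samples:
            sp = sample_species[s]
            species_seen.setdefault(sp)
            names.extend([(sp, s, 1), (sp, s, 2)])
        bases = np.array([c for _, c in sites]).T  # rows x sites
        order = sorted(range(len(names)), key=lambda i: names[i])
        if locus_lengths and locus_id in locus_lengths:
            length = locus_lengths[locus_id]
        else:
            length = int(positions.max()) + 1
        loci.append(LocusAlignment(
            locus_id=locus_id, length_bp=length,
            names=[names[i] for i in order],
            positions=positions, bases=bases[order],
        ))
    loci.sort(key=lambda loc: loc.locus_id)
    order = species_order or tuple(sorted(species_seen))
    return LocusDataset(loci=loci, species_order=order)


# ---------------------------------------------------------------------------
# locus table

def write_locus_table(dataset: LocusDataset, path) -> None:
    """Tab-separated locus table: id, length, SNP count, per-species counts."""
    header = ["locus_id", "length_bp", "n_snps"] + [
        f"n_seq_{sp}" for sp in dataset.species_order
    ]
    rows = [header]
    for loc in dataset.loci:
        counts = {sp: 0 for sp in dataset.species_order}
        for sp, _, _ in loc.names:
            counts[sp] += 1
        rows.append([loc.locus_id, str(loc.length_bp),
                     str(loc.bases.shape[1])]
                    + [str(counts[sp]) for sp in dataset.species_order])
    Path(path).write_text("\n".join("\t".join(r) for r in rows) + "\n")


def read_locus_table(path) -> dict[str, int]:
    """Locus id -> length mapping from a locus table."""
    lines = Path(path).read_text().strip().splitlines()
    out = {}
    for line in lines[1:]:
        parts = line.split("\t")
        out[parts[0]] = int(parts[1])
    return out
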