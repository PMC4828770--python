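"""Genotype matrices, population maps and the filters applied before analysis.

The package's common currency is the :class:`GenotypeMatrix`: an ordered set
of SNP loci by an ordered set of diploid individuals, each cell holding an
unordered pair of allele codes or MISSING.  Genotypes are unphased; "allele
order" within a call is simply the storage order of the input file (VCF GT
field order, TSV column order), which makes haplotype splitting deterministic
for a fixed input.  MISSING is a first-class value and is never imputed.

RAD loci are anonymous: locus identifiers are opaque strings, no genomic
arithmetic is performed and strand is never complemented.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "PopulationMap",
    "HaplotypePair",
    "read_genotypes",
    "read_genotype_tsv",
    "read_vcf",
    "write_genotype_tsv",
    "write_vcf",
    "read_population_map",
    "write_population_map",
    "filter_complete_biallelic",
    "one_snp_per_locus",
    "split_haplotypes",
]

#: Sentinel allele index for a missing call.
MISSING: int = -1


class GenotypeParseError(ValueError):
    """Raised when an input file cannot be parsed; names the offending record."""


@dataclass
class GenotypeMatrix:
    """Loci x individuals diploid calls, coded as indices into per-locus labels.

    Parameters
    ----------
    locus_ids
        Ordered, unique locus identifiers (opaque strings).
    individual_ids
        Ordered, unique sample identifiers.
    calls
        ``(n_loci, n_individuals, 2)`` int array.  Entry ``calls[l, i, k]`` is
        an index into ``allele_labels[l]`` or :data:`MISSING`.  The two slots
        preserve the storage order of the source file.
    allele_labels
        Per locus, the tuple of observed allele codes in first-appearance
        order.  A locus is biallelic iff it has exactly two labels.
    """

    locus_ids: list[str]
    individual_ids: list[str]
    calls: np.ndarray
    allele_labels: list[tuple[str, ...]]
    _ind_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int16)
        if self.calls.shape != (len(self.locus_ids), len(self.individual_ids), 2):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.locus_ids)} loci x {len(self.individual_ids)} individuals"
            )
        if len(set(self.individual_ids)) != len(self.individual_ids):
            dupes = pd.Series(self.individual_ids)
            raise ValueError(
                "duplicate individual ids: "
                + ", ".join(sorted(dupes[dupes.duplicated()].unique()))
            )
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise ValueError("duplicate locus ids")
        for l, labels in enumerate(self.allele_labels):
            valid = self.calls[l][self.calls[l] != MISSING]
            if valid.size and (valid.min() < 0 or valid.max() >= len(labels)):
                raise ValueError(f"locus {self.locus_ids[l]}: call index outside allele labels")
        self._ind_index = {ind: i for i, ind in enumerate(self.individual_ids)}

    # -- basic geometry -----------------------------------------------------

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    def individual_index(self, individual: str) -> int:
        try:
            return self._ind_index[individual]
        except KeyError:
            raise KeyError(f"unknown individual {individual!r}") from None

    # -- per-locus flags ----------------------------------------------------

    def n_alleles(self) -> np.ndarray:
        """Number of observed allele labels per locus."""
        return np.array([len(lab) for lab in self.allele_labels])

    def biallelic_mask(self) -> np.ndarray:
        """True for loci with exactly two observed alleles."""
        return self.n_alleles() == 2

    def missing_mask(self) -> np.ndarray:
        """True for loci with at least one MISSING call."""
        return (self.calls == MISSING).any(axis=(1, 2))

    # -- subsetting ---------------------------------------------------------

    def subset_loci(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            locus_ids=[self.locus_ids[i] for i in index],
            individual_ids=list(self.individual_ids),
            calls=self.calls[index].copy(),
            allele_labels=[self.allele_labels[i] for i in index],
        )

    def subset_individuals(self, individuals: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.individual_index(i) for i in individuals]
        sub = self.calls[:, idx, :]
        # re-normalize labels to those observed in the subset
        return GenotypeMatrix.from_labels(
            self.locus_ids,
            list(individuals),
            self._decode(sub),
        )

    # -- label/code conversion ----------------------------------------------

    def _decode(self, calls: np.ndarray) -> np.ndarray:
        """Index-coded calls -> object array of label strings ('.' for MISSING)."""
        out = np.empty(calls.shape, dtype=object)
        for l in range(calls.shape[0]):
            labels = self.allele_labels[l]
            for k in (0, 1):
                col = calls[l, :, k]
                out[l, :, k] = [labels[c] if c != MISSING else "." for c in col]
        return out

    def decoded_calls(self) -> np.ndarray:
        """Calls as an ``(n_loci, n_individuals, 2)`` array of label strings."""
        return self._decode(self.calls)

    @classmethod
    def from_labels(
        cls,
        locus_ids: Sequence[str],
        individual_ids: Sequence[str],
        label_calls: np.ndarray,
        label_order: Sequence[Sequence[str]] | None = None,
    ) -> "GenotypeMatrix":
        """Build from an array of allele-label strings ('.' = missing).

        ``label_order`` optionally fixes the coding order per locus (e.g. VCF
        REF/ALT order); labels absent from all calls are dropped so the label
        set is always the observed one.
        """
        label_calls = np.asarray(label_calls, dtype=object)
        n_loci, n_ind = label_calls.shape[0], label_calls.shape[1]
        calls = np.full((n_loci, n_ind, 2), MISSING, dtype=np.int16)
        allele_labels: list[tuple[str, ...]] = []
        for l in range(n_loci):
            flat = label_calls[l].ravel()
            observed = [a for a in dict.fromkeys(flat) if a != "."]
            if label_order is not None:
                ordered = [a for a in label_order[l] if a in observed]
                ordered += [a for a in observed if a not in ordered]
                observed = ordered
            code = {a: i for i, a in enumerate(observed)}
            for i in range(n_ind):
                for k in (0, 1):
                    a = label_calls[l, i, k]
                    if a != ".":
                        calls[l, i, k] = code[a]
            allele_labels.append(tuple(observed))
        return cls(list(locus_ids), list(individual_ids), calls, allele_labels)


@dataclass
class PopulationMap:
    """Assignment of each individual to exactly one group (taxon)."""

    assignments: dict[str, str]

    @property
    def groups(self) -> dict[str, list[str]]:
        """Group label -> ordered member list (input order preserved)."""
        out: dict[str, list[str]] = {}
        for ind, grp in self.assignments.items():
            out.setdefault(grp, []).append(ind)
        return out

    def members(self, group: str) -> list[str]:
        members = self.groups.get(group)
        if not members:
            raise KeyError(f"group {group!r} is empty or unknown")
        return members

    def validate(self, gm: GenotypeMatrix) -> None:
        missing = [i for i in gm.individual_ids if i not in self.assignments]
        if missing:
            raise ValueError(f"individuals without group assignment: {missing}")


@dataclass
class HaplotypePair:
    """One individual's two allele vectors in storage order (unphased data).

    ``hap_a`` holds the first-stored allele at every locus, ``hap_b`` the
    second; at homozygous loci the two agree.  The pairing is arbitrary but
    deterministic for a fixed input file, which is what the two-run D-test
    scheme requires.
    """

    individual: str
    locus_ids: list[str]
    hap_a: np.ndarray
    hap_b: np.ndarray
    phase_convention: str = "as-stored order"


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path, format: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from VCF or long-format TSV.

    The format is inferred from the file extension when not given
    (``.vcf`` -> VCF, anything else -> TSV).
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix == ".vcf" else "tsv"
    if format == "vcf":
        return read_vcf(path)
    if format == "tsv":
        return read_genotype_tsv(path)
    raise ValueError(f"unknown format {format!r}")


def read_genotype_tsv(path: str | Path) -> GenotypeMatrix:
    """Read the long genotype TSV: ``locus  individual  allele1  allele2``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["locus", "individual", "allele1", "allele2"]
    if list(df.columns) != expected:
        raise GenotypeParseError(
            f"{path}: expected header {expected}, found {list(df.columns)}"
        )
    if df.isna().any().any():
        bad = int(df.isna().any(axis=1).idxmax()) + 2  # +2: header + 1-based
        raise GenotypeParseError(f"{path}: malformed record at line {bad}")
    dup = df.duplicated(subset=["locus", "individual"])
    if dup.any():
        l, i = df.loc[dup.idxmax(), ["locus", "individual"]]
        raise GenotypeParseError(f"{path}: duplicate call for locus {l}, individual {i}")
    locus_ids = list(dict.fromkeys(df["locus"]))
    individual_ids = list(dict.fromkeys(df["individual"]))
    l_idx = {l: i for i, l in enumerate(locus_ids)}
    i_idx = {s: i for i, s in enumerate(individual_ids)}
    labels = np.full((len(locus_ids), len(individual_ids), 2), ".", dtype=object)
    li = df["locus"].map(l_idx).to_numpy()
    ii = df["individual"].map(i_idx).to_numpy()
    labels[li, ii, 0] = df["allele1"].to_numpy()
    labels[li, ii, 1] = df["allele2"].to_numpy()
    # half-missing calls (one '.') are treated as fully missing
    half = (labels[:, :, 0] == ".") ^ (labels[:, :, 1] == ".")
    labels[half, :] = "."
    return GenotypeMatrix.from_labels(locus_ids, individual_ids, labels)


def write_genotype_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    decoded = gm.decoded_calls()
    rows = []
    for l, locus in enumerate(gm.locus_ids):
        for i, ind in enumerate(gm.individual_ids):
            rows.append((locus, ind, decoded[l, i, 0], decoded[l, i, 1]))
    pd.DataFrame(rows, columns=["locus", "individual", "allele1", "allele2"]).to_csv(
        path, sep="\t", index=False
    )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read biallelic-or-more SNP records from a VCF via cyvcf2.

    CHROM is interpreted as the RAD locus id and POS as the site offset; each
    site becomes one matrix row with id ``CHROM:POS``.  Multi-allelic records
    are retained (they carry >2 labels and are flagged non-biallelic, to be
    dropped by :func:`filter_complete_biallelic`).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individual_ids = list(vcf.samples)
    locus_ids: list[str] = []
    label_rows: list[np.ndarray] = []
    orders: list[list[str]] = []
    for var in vcf:
        locus_ids.append(f"{var.CHROM}:{var.POS}")
        alleles = [var.REF] + list(var.ALT)
        row = np.full((len(individual_ids), 2), ".", dtype=object)
        for i, gt in enumerate(var.genotypes):
            a, b = gt[0], gt[1]
            if a >= 0 and b >= 0:
                row[i, 0] = alleles[a]
                row[i, 1] = alleles[b]
        label_rows.append(row)
        orders.append(alleles)
    vcf.close()
    if not locus_ids:
        warnings.warn(f"{path}: no variant records")
    labels = (
        np.stack(label_rows) if label_rows else np.empty((0, len(individual_ids), 2), object)
    )
    return GenotypeMatrix.from_labels(locus_ids, individual_ids, labels, label_order=orders)


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=radmix
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal GT-only VCF 4.2; locus ids ``chrom:pos`` are split back."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.individual_ids)
            + "\n"
        )
        for l, locus in enumerate(gm.locus_ids):
            chrom, _, pos = locus.rpartition(":")
            if not chrom or not pos.isdigit():
                chrom, pos = locus, "1"
            labels = gm.allele_labels[l]
            ref = labels[0] if labels else "N"
            alt = ",".join(labels[1:]) if len(labels) > 1 else "."
            gts = []
            for i in range(gm.n_individuals):
                a, b = gm.calls[l, i]
                gts.append("./." if a == MISSING else f"{a}/{b}")
            fh.write(
                f"{chrom}\t{pos}\t{locus}\t{ref}\t{alt}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_population_map(path: str | Path) -> PopulationMap:
    """Read the two-column ``individual<TAB>group`` map (header optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=None)
    if df.shape[1] != 2:
        raise GenotypeParseError(f"{path}: expected 2 tab-separated columns")
    if list(df.iloc[0]) == ["individual", "group"]:
        df = df.iloc[1:]
    if df[0].duplicated().any():
        dupes = df.loc[df[0].duplicated(), 0].tolist()
        raise GenotypeParseError(f"{path}: individuals listed twice: {dupes}")
    return PopulationMap(dict(zip(df[0], df[1])))


def write_population_map(pm: PopulationMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("individual\tgroup\n")
        for ind, grp in pm.assignments.items():
            fh.write(f"{ind}\t{grp}\n")


# ---------------------------------------------------------------------------
# Filters and haplotype splitting
# ---------------------------------------------------------------------------

def filter_complete_biallelic(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Keep exactly the loci that are biallelic and genotyped in all samples.

    This mirrors the standard RADseq practice of analysing only loci called
    in every individual; it is idempotent and order-preserving.
    """
    keep = gm.biallelic_mask() & ~gm.missing_mask()
    if not keep.any():
        warnings.warn("no loci pass the complete-biallelic filter")
    return gm.subset_loci(np.flatnonzero(keep))


def one_snp_per_locus(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Keep the first site per RAD locus id (the ``chrom`` part of ``chrom:pos``)."""
    seen: set[str] = set()
    keep = []
    for i, locus in enumerate(gm.locus_ids):
        chrom = locus.rpartition(":")[0] or locus
        if chrom not in seen:
            seen.add(chrom)
            keep.append(i)
    return gm.subset_loci(keep)


def split_haplotypes(gm: GenotypeMatrix, individual: str) -> HaplotypePair:
    """Split one individual's genotypes into the two stored allele vectors.

    Requires a complete matrix: a MISSING call is an error because the
    complete-matrix filter must run first.
    """
    i = gm.individual_index(individual)
    calls = gm.calls[:, i, :]
    if (calls == MISSING).any():
        bad = gm.locus_ids[int(np.argmax((calls == MISSING).any(axis=1)))]
        raise ValueError(
            f"individual {individual!r} has a MISSING call at locus {bad}; "
            "apply filter_complete_biallelic first"
        )
    hap_a = np.array(
        [gm.allele_labels[l][calls[l, 0]] for l in range(gm.n_loci)], dtype=object
    )
    hap_b = np.array(
        [gm.allele_labels[l][calls[l, 1]] for l in range(gm.n_loci)], dtype=object
    )
    return HaplotypePair(individual, list(gm.locus_ids), hap_a, hap_b)
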