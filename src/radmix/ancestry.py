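"""Diagnostic-locus hybrid index q and inter-source heterozygosity Q12.

At loci fixed for alternate alleles between two parental taxa, each gene
copy in a putative hybrid can be assigned unambiguously to one parental
source.  The hybrid index q is the proportion of B-type gene copies over the
panel; Q12 is the proportion of panel loci heterozygous A-type/B-type.
Together they place an individual in the "hybrid triangle": Q12 = 2*min(q,
1-q) is attained when one parent of the individual is a pure parental (F1s
and first backcrosses), while a randomly mating admixed population settles
at the Hardy-Weinberg expectation Q12 = 2q(1-q).  Points well below the
maximum line are evidence against ongoing hybridization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, PopulationMap

__all__ = [
    "DiagnosticPanel",
    "AncestryProfile",
    "find_diagnostic_loci",
    "ancestry_profile",
    "ancestry_table",
    "q12_bounds",
    "triangle_curves",
]


@dataclass
class DiagnosticPanel:
    """Loci fixed for alternate alleles between parent groups A and B.

    ``a_allele``/``b_allele`` give, per panel locus, the allele code index
    diagnostic for parent A and parent B respectively.
    """

    locus_indices: np.ndarray
    locus_ids: list[str]
    a_allele: np.ndarray
    b_allele: np.ndarray
    parent_a: str
    parent_b: str

    def __len__(self) -> int:
        return len(self.locus_ids)


@dataclass
class AncestryProfile:
    """Per-individual hybrid index and inter-source heterozygosity."""

    individual: str
    q: float
    q12: float
    n_loci: int


def find_diagnostic_loci(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    parent_a: str,
    parent_b: str,
    max_minor_freq: float = 0.0,
) -> DiagnosticPanel:
    """Loci where the two parent samples are fixed for different alleles.

    "Fixed" means fixed in the sample; with ``max_minor_freq`` > 0 an allele
    whose within-parent frequency is at most that threshold is tolerated
    (strict fixation, the default, uses 0).
    """
    if not gm.biallelic_mask().all() or gm.missing_mask().any():
        raise ValueError("diagnostic scan requires a complete biallelic matrix")
    idx_a = [gm.individual_index(i) for i in pm.members(parent_a)]
    idx_b = [gm.individual_index(i) for i in pm.members(parent_b)]
    freq_a = gm.calls[:, idx_a, :].reshape(gm.n_loci, -1).mean(axis=1)
    freq_b = gm.calls[:, idx_b, :].reshape(gm.n_loci, -1).mean(axis=1)
    a_fixed0 = freq_a <= max_minor_freq
    a_fixed1 = freq_a >= 1 - max_minor_freq
    b_fixed0 = freq_b <= max_minor_freq
    b_fixed1 = freq_b >= 1 - max_minor_freq
    diag = (a_fixed0 & b_fixed1) | (a_fixed1 & b_fixed0)
    indices = np.flatnonzero(diag)
    if len(indices) == 0:
        warnings.warn(f"no diagnostic loci between {parent_a} and {parent_b}")
    a_allele = np.where(a_fixed1[indices], 1, 0).astype(np.int16)
    return DiagnosticPanel(
        locus_indices=indices,
        locus_ids=[gm.locus_ids[i] for i in indices],
        a_allele=a_allele,
        b_allele=(1 - a_allele).astype(np.int16),
        parent_a=parent_a,
        parent_b=parent_b,
    )


def ancestry_profile(
    gm: GenotypeMatrix, panel: DiagnosticPanel, individual: str
) -> AncestryProfile:
    """q and Q12 for one individual over the diagnostic panel.

    q counts B-type gene copies out of 2L; Q12 counts loci heterozygous for
    one A-type and one B-type allele out of L.
    """
    if len(panel) == 0:
        raise ValueError("empty diagnostic panel")
    i = gm.individual_index(individual)
    calls = gm.calls[panel.locus_indices, i, :]  # (L, 2) codes
    is_b = calls == panel.b_allele[:, None]
    q = float(is_b.mean())
    het_ab = is_b[:, 0] != is_b[:, 1]
    q12 = float(het_ab.mean())
    return AncestryProfile(individual, q, q12, len(panel))


def ancestry_table(
    gm: GenotypeMatrix,
    panel: DiagnosticPanel,
    individuals: list[str] | None = None,
) -> pd.DataFrame:
    """Per-individual q, Q12 and panel size, as a tidy table."""
    if individuals is None:
        individuals = list(gm.individual_ids)
    rows = [ancestry_profile(gm, panel, ind) for ind in individuals]
    return pd.DataFrame(
        {
            "individual": [r.individual for r in rows],
            "q": [r.q for r in rows],
            "Q12": [r.q12 for r in rows],
            "L": [r.n_loci for r in rows],
        }
    ).set_index("individual")


def q12_bounds(q):
    """Triangle bounds at hybrid index q.

    Returns ``(q12_max, q12_hwe)``: the maximum inter-source heterozygosity
    2*min(q, 1-q), attained when one parent is a pure parental individual,
    and the Hardy-Weinberg expectation 2q(1-q) for a randomly mating
    admixed population.  Accepts scalars or arrays.
    """
    q = np.asarray(q, dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise ValueError("q must lie in [0, 1]")
    q12_max = 2.0 * np.minimum(q, 1.0 - q)
    q12_hwe = 2.0 * q * (1.0 - q)
    if q.ndim == 0:
        return float(q12_max), float(q12_hwe)
    return q12_max, q12_hwe


def triangle_curves(n_points: int = 101) -> pd.DataFrame:
    """The two bound curves sampled on a regular q grid (for plotting)."""
    q = np.linspace(0.0, 1.0, n_points)
    q12_max, q12_hwe = q12_bounds(q)
    return pd.DataFrame({"q": q, "Q12_max": q12_max, "Q12_hwe": q12_hwe})
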