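"""Synthetic four-taxon RADseq SNP scenarios with ILS and admixture.

The generator produces complete biallelic genotype matrices on the species
tree (((P1, H), P3), Outgroup), where H is the putative hybrid group.  It is
a frequency-drift simulator, not a coalescent: each locus starts from an
ancestral derived-allele frequency drawn from a U-shaped Beta(0.5, 0.5),
and every branch perturbs the frequency by Balding-Nichols beta drift with a
branch-specific intensity c in (0, 1).  Shared ancestral polymorphism
surviving the splits yields discordant (ABBA/BABA) site patterns without any
gene flow — the incomplete-lineage-sorting background the D statistic must
see through — while the admixture fraction f injects a real pulse from P3
into H.  Two modes:

frequency
    The hybrid population frequency is the convex combination
    (1 - f) * p_H-sister + f * p_P3, optionally followed by ``n_generations``
    of binomial Wright-Fisher drift at effective size ``ne``; genotypes are
    then drawn binomially.  Good for population-level expectations.

mosaic
    Hybrid individuals are explicit per-locus mosaics of haplotypes copied
    from the simulated P1 and P3 sample pools, built from a founder
    generation (fraction f of founder haplotypes are P3-source, paired so
    that f = 0.5 with no later mating gives pure F1s) followed by
    ``n_generations`` rounds of random mating with free recombination in a
    breeding pool.  The returned truth records every gene copy's source, so
    hybrid-index and f-recovery tests have exact ground truth.

All randomness flows from ``ScenarioParams.seed``; output is byte-identical
across runs for a fixed parameter set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .genotypes import (
    GenotypeMatrix,
    PopulationMap,
    write_genotype_tsv,
    write_population_map,
    write_vcf,
)

__all__ = [
    "ScenarioParams",
    "ScenarioTruth",
    "admixed_frequencies",
    "simulate_frequency_scenario",
    "simulate_mosaic_hybrids",
    "simulate_scenario",
    "write_scenario",
]

_NUCS = np.array(["A", "C", "G", "T"])


@dataclass
class ScenarioParams:
    """Parameters of one simulated study.

    Defaults mirror the emulated study design: 977 complete polymorphic
    biallelic loci over P1 = 8, hybrid = 12, P3 = 12 and outgroup = 3
    diploid samples.  Branch drift intensities ``c_*`` are calibrated so
    that the P1-clade vs P3 differentiation lands at Weir-Cockerham
    Fst ~ 0.6-0.75 and P1 vs H at ~ 0.2, the magnitudes of the emulated
    system, making simulated D and Fst values interpretable on the same
    scale.
    """

    n_loci: int = 977
    n_p1: int = 8
    n_hybrid: int = 12
    n_p3: int = 12
    n_outgroup: int = 3
    c_p1: float = 0.2
    c_hybrid: float = 0.2
    c_split: float = 0.5  # branch from the (P1,H)+P3 ancestor to the (P1,H) ancestor
    c_p3: float = 0.65
    c_ingroup: float = 0.3  # root -> ingroup ancestor
    c_outgroup: float = 0.65
    f: float = 0.0
    n_generations: int = 0
    ne: int = 100  # post-admixture Wright-Fisher size (frequency mode)
    pool_size: int = 100  # breeding pool of hybrid individuals (mosaic mode)
    mode: str = "frequency"
    seed: int = 0
    group_names: tuple[str, str, str, str] = ("P1", "H", "P3", "OUT")

    def __post_init__(self) -> None:
        for name in ("c_p1", "c_hybrid", "c_split", "c_p3", "c_ingroup", "c_outgroup"):
            c = getattr(self, name)
            if not 0 < c < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {c}")
        if not 0 <= self.f <= 1:
            raise ValueError(f"f must lie in [0, 1], got {self.f}")
        if min(self.n_p1, self.n_hybrid, self.n_p3, self.n_outgroup) < 1:
            raise ValueError("sample sizes must be >= 1")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.mode not in ("frequency", "mosaic"):
            raise ValueError(f"mode must be 'frequency' or 'mosaic', got {self.mode!r}")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")


@dataclass
class ScenarioTruth:
    """Ground truth recorded by the generator.

    ``hybrid_sources`` (mosaic mode only) is ``(n_hybrid, 2, n_loci)`` with
    1 where the gene copy was drawn from the P3 pool and 0 for the P1-side
    pool; ``ancestral_allele`` is the root-state label per locus.
    """

    f: float
    ancestral_allele: list[str]
    hybrid_ids: list[str] = field(default_factory=list)
    hybrid_sources: np.ndarray | None = None

    def source_fraction(self) -> float:
        """Realized fraction of P3-labelled hybrid gene copies."""
        if self.hybrid_sources is None:
            raise ValueError("per-copy truth only exists in mosaic mode")
        return float(self.hybrid_sources.mean())


def _drift(rng: np.random.Generator, p: np.ndarray, c: float) -> np.ndarray:
    """Balding-Nichols beta drift: Beta(p(1-c)/c, (1-p)(1-c)/c)."""
    p = np.clip(p, 1e-9, 1 - 1e-9)
    scale = (1 - c) / c
    return rng.beta(p * scale, (1 - p) * scale)


def _tree_frequencies(rng, params: ScenarioParams, n: int):
    """Per-locus derived frequencies for P1, H-sister, P3 and outgroup."""
    p_root = rng.beta(0.5, 0.5, size=n)
    p_ing = _drift(rng, p_root, params.c_ingroup)
    p_out = _drift(rng, p_root, params.c_outgroup)
    p_p3 = _drift(rng, p_ing, params.c_p3)
    p_split = _drift(rng, p_ing, params.c_split)
    p_p1 = _drift(rng, p_split, params.c_p1)
    p_h = _drift(rng, p_split, params.c_hybrid)
    return p_p1, p_h, p_p3, p_out


def admixed_frequencies(rng, params: ScenarioParams, n: int):
    """Per-locus sampled-population frequencies (P1, H, P3, outgroup).

    The hybrid frequency is the admixture pulse (1-f)*p_H-sister + f*p_P3,
    followed by ``n_generations`` of binomial Wright-Fisher drift at size
    ``ne``.  With f = 1 and no post-admixture generations the hybrid
    frequencies equal P3's pre-sampling frequencies exactly.
    """
    p_p1, p_h0, p_p3, p_out = _tree_frequencies(rng, params, n)
    p_h = (1 - params.f) * p_h0 + params.f * p_p3
    for _ in range(params.n_generations):
        p_h = rng.binomial(2 * params.ne, p_h) / (2 * params.ne)
    return p_p1, p_h, p_p3, p_out


def _draw_genotypes(rng, p: np.ndarray, n_ind: int) -> np.ndarray:
    """(L, n_ind, 2) array of 0/1 gene copies, 1 = derived."""
    return (rng.random((p.size, n_ind, 2)) < p[:, None, None]).astype(np.int16)


def _ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i + 1:02d}" for i in range(n)]


def _assemble(params: ScenarioParams, rng, calls_by_group) -> tuple[GenotypeMatrix, PopulationMap, list[str]]:
    """Stack group calls into a GenotypeMatrix with random nucleotide labels."""
    calls = np.concatenate([c for _, c in calls_by_group], axis=1)
    n_loci = calls.shape[0]
    anc = rng.integers(0, 4, size=n_loci)
    der = (anc + rng.integers(1, 4, size=n_loci)) % 4
    allele_labels = [(_NUCS[a], _NUCS[d]) for a, d in zip(anc, der)]
    individual_ids: list[str] = []
    assignments: dict[str, str] = {}
    for (name, group_calls), prefix in zip(calls_by_group, ("P1_", "H_", "P3_", "O_")):
        ids = _ids(prefix, group_calls.shape[1])
        individual_ids += ids
        for i in ids:
            assignments[i] = name
    locus_ids = [f"L{i + 1:05d}:1" for i in range(n_loci)]
    gm = GenotypeMatrix(locus_ids, individual_ids, calls, allele_labels)
    return gm, PopulationMap(assignments), [lab[0] for lab in allele_labels]


def simulate_frequency_scenario(
    params: ScenarioParams,
) -> tuple[GenotypeMatrix, PopulationMap, ScenarioTruth]:
    """Frequency-mode scenario: admixture acts on population frequencies.

    Loci monomorphic across every sampled individual are dropped and redrawn
    until the matrix holds exactly ``n_loci`` polymorphic, complete loci.
    """
    if params.mode != "frequency":
        raise ValueError("params.mode must be 'frequency'")
    rng = np.random.default_rng(params.seed)
    blocks = {name: [] for name in params.group_names}
    collected = 0
    while collected < params.n_loci:
        batch = max(2 * (params.n_loci - collected), 64)
        p_p1, p_h, p_p3, p_out = admixed_frequencies(rng, params, batch)
        g_p1 = _draw_genotypes(rng, p_p1, params.n_p1)
        g_h = _draw_genotypes(rng, p_h, params.n_hybrid)
        g_p3 = _draw_genotypes(rng, p_p3, params.n_p3)
        g_out = _draw_genotypes(rng, p_out, params.n_outgroup)
        allc = np.concatenate([g_p1, g_h, g_p3, g_out], axis=1).reshape(batch, -1)
        poly = (allc.min(axis=1) == 0) & (allc.max(axis=1) == 1)
        keep = np.flatnonzero(poly)[: params.n_loci - collected]
        for name, g in zip(params.group_names, (g_p1, g_h, g_p3, g_out)):
            blocks[name].append(g[keep])
        collected += len(keep)
    calls_by_group = [
        (name, np.concatenate(blocks[name], axis=0)) for name in params.group_names
    ]
    gm, pm, anc = _assemble(params, rng, calls_by_group)
    truth = ScenarioTruth(
        f=params.f,
        ancestral_allele=anc,
        hybrid_ids=pm.members(params.group_names[1]),
    )
    return gm, pm, truth


def simulate_mosaic_hybrids(
    params: ScenarioParams,
) -> tuple[GenotypeMatrix, PopulationMap, ScenarioTruth]:
    """Mosaic-mode scenario: hybrids are explicit copies of parental haplotypes.

    Parental and outgroup samples are simulated as in frequency mode with no
    gene flow; each hybrid gene copy then descends from founder haplotypes
    that copied, locus by locus, from the P3 sample pool (source label 1) or
    the P1 sample pool (label 0).  ``n_generations`` rounds of random mating
    with free recombination let Q12 decay from the founder geometry toward
    the Hardy-Weinberg value 2f(1-f).
    """
    if params.mode != "mosaic":
        raise ValueError("params.mode must be 'mosaic'")
    rng = np.random.default_rng(params.seed)
    L = params.n_loci

    # parental + outgroup genotypes, polymorphic across those samples
    parts = {"p1": [], "p3": [], "out": []}
    collected = 0
    while collected < L:
        batch = max(2 * (L - collected), 64)
        p_p1, _, p_p3, p_out = _tree_frequencies(rng, params, batch)
        g_p1 = _draw_genotypes(rng, p_p1, params.n_p1)
        g_p3 = _draw_genotypes(rng, p_p3, params.n_p3)
        g_out = _draw_genotypes(rng, p_out, params.n_outgroup)
        allc = np.concatenate([g_p1, g_p3, g_out], axis=1).reshape(batch, -1)
        poly = (allc.min(axis=1) == 0) & (allc.max(axis=1) == 1)
        keep = np.flatnonzero(poly)[: L - collected]
        for key, g in zip(("p1", "p3", "out"), (g_p1, g_p3, g_out)):
            parts[key].append(g[keep])
        collected += len(keep)
    g_p1 = np.concatenate(parts["p1"], axis=0)
    g_p3 = np.concatenate(parts["p3"], axis=0)
    g_out = np.concatenate(parts["out"], axis=0)

    pool_p1 = g_p1.reshape(L, -1).T  # (2*n_p1, L) haplotype pool
    pool_p3 = g_p3.reshape(L, -1).T

    # founder generation: pure-source haplotypes, P3 copies paired one per
    # individual first so f = 0.5 with g = 0 yields all-F1 geometry
    n_pool = params.pool_size
    m = int(round(params.f * 2 * n_pool))
    sources = np.zeros((n_pool, 2, L), dtype=np.int8)
    for h in range(min(m, n_pool)):
        sources[h, 1, :] = 1
    for h in range(max(0, m - n_pool)):
        sources[h, 0, :] = 1

    alleles = np.empty((n_pool, 2, L), dtype=np.int16)
    donors_p1 = rng.integers(0, pool_p1.shape[0], size=(n_pool, 2, L))
    donors_p3 = rng.integers(0, pool_p3.shape[0], size=(n_pool, 2, L))
    cols = np.broadcast_to(np.arange(L), (n_pool, 2, L))
    alleles = np.where(
        sources == 1, pool_p3[donors_p3, cols], pool_p1[donors_p1, cols]
    ).astype(np.int16)

    for _ in range(params.n_generations):
        mothers = rng.integers(0, n_pool, size=n_pool)
        fathers = rng.integers(0, n_pool, size=n_pool)
        new_alleles = np.empty_like(alleles)
        new_sources = np.empty_like(sources)
        for slot, parents in ((0, mothers), (1, fathers)):
            bits = rng.integers(0, 2, size=(n_pool, 1, L))
            new_alleles[:, slot, :] = np.take_along_axis(alleles[parents], bits, axis=1)[:, 0, :]
            new_sources[:, slot, :] = np.take_along_axis(sources[parents], bits, axis=1)[:, 0, :]
        alleles, sources = new_alleles, new_sources

    pick = rng.choice(n_pool, size=params.n_hybrid, replace=False)
    g_h = alleles[pick].transpose(2, 0, 1)  # (L, n_hybrid, 2)
    h_sources = sources[pick]

    calls_by_group = list(
        zip(params.group_names, (g_p1, g_h, g_p3, g_out))
    )
    gm, pm, anc = _assemble(params, rng, calls_by_group)
    truth = ScenarioTruth(
        f=params.f,
        ancestral_allele=anc,
        hybrid_ids=pm.members(params.group_names[1]),
        hybrid_sources=h_sources,
    )
    return gm, pm, truth


def simulate_scenario(
    params: ScenarioParams,
) -> tuple[GenotypeMatrix, PopulationMap, ScenarioTruth]:
    """Dispatch on ``params.mode``."""
    if params.mode == "frequency":
        return simulate_frequency_scenario(params)
    return simulate_mosaic_hybrids(params)


def write_scenario(
    outdir: str | Path,
    gm: GenotypeMatrix,
    pm: PopulationMap,
    truth: ScenarioTruth,
    params: ScenarioParams,
    format: str = "tsv",
) -> dict[str, Path]:
    """Write genotypes, population map, truth table and params to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    if format == "vcf":
        paths["genotypes"] = outdir / "genotypes.vcf"
        write_vcf(gm, paths["genotypes"])
    else:
        paths["genotypes"] = outdir / "genotypes.tsv"
        write_genotype_tsv(gm, paths["genotypes"])
    paths["popmap"] = outdir / "popmap.tsv"
    write_population_map(pm, paths["popmap"])

    paths["truth"] = outdir / "truth.tsv"
    with open(paths["truth"], "w") as fh:
        fh.write("locus\tancestral_allele\tp3_copy_fraction\n")
        for l, locus in enumerate(gm.locus_ids):
            frac = (
                f"{truth.hybrid_sources[:, :, l].mean():.6f}"
                if truth.hybrid_sources is not None
                else "NA"
            )
            fh.write(f"{locus}\t{truth.ancestral_allele[l]}\t{frac}\n")

    paths["params"] = outdir / "params.yaml"
    d = asdict(params)
    d["group_names"] = list(d["group_names"])
    with open(paths["params"], "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
    return paths
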