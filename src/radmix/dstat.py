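"""Individual-based ABBA/BABA tests, admixture fraction f, reference-bias
analysis, and population-frequency D with binomial bootstrap.

The four-taxon test places individuals on the species tree
(((P1, P2), P3, Outgroup)).  At a biallelic site, the pattern ABBA (P2 and
P3 share one allele, P1 and the outgroup the other) and the pattern BABA
(P1 and P3 share) are equally probable under incomplete lineage sorting
alone; gene flow from P3 into P2 inflates ABBA.  Patterson's D is
(nABBA - nBABA) / (nABBA + nBABA).

Rather than testing one representative per taxon, every combination of
reference individuals (P1 x P3 x Outgroup) is tested for every P2 candidate,
and each combination is run twice so both alleles of the unphased diploid
genotypes contribute: run 1 uses the first-stored allele of all four
individuals, run 2 the second.  Control configurations draw the P2
individual from the P1 group (zero gene flow) and from the P3 group
(maximal gene flow, leave-one-out); the latter calibrate the admixture
fraction f = S_i / S_max, where S = nABBA - nBABA is the introgression
excess and S_max its mean over the maximal-gene-flow controls.

A population-level D computed from derived-allele frequencies
(derived = the least frequent allele in the outgroup sample) complements
the individual tests, with significance from a binomial bootstrap over
per-population allele frequencies.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix, PopulationMap

__all__ = [
    "QuartetConfig",
    "QuartetSpec",
    "DSummary",
    "PopulationDResult",
    "count_site_patterns",
    "d_from_counts",
    "enumerate_tests",
    "run_individual_dstat",
    "admixture_fraction",
    "reference_bias_analysis",
    "population_dstat",
    "bootstrap_population_d",
]

ROLE_CANDIDATE = "candidate"
ROLE_CONTROL_ZERO = "control_zero"
ROLE_CONTROL_MAX = "control_max"


@dataclass
class QuartetConfig:
    """Role assignment for the four-taxon tests.

    ``p2_candidates`` lists the putative-hybrid groups tested as P2.  With
    ``include_controls`` (default) individuals of the P1 group and of the P3
    group are additionally run as P2 (leave-one-out from their own reference
    pool), providing the zero- and maximal-gene-flow calibration points.
    ``allele_scheme`` is "paired" (two runs: all four individuals contribute
    their first-stored, then their second-stored allele) or "all_haplotypes"
    (all 16 haplotype assignments per individual combination).
    """

    p1: str
    p3: str
    outgroup: str
    p2_candidates: list[str] = field(default_factory=list)
    allele_scheme: str = "paired"
    include_controls: bool = True

    def __post_init__(self) -> None:
        if self.allele_scheme not in ("paired", "all_haplotypes"):
            raise ValueError(f"unknown allele scheme {self.allele_scheme!r}")


@dataclass(frozen=True)
class QuartetSpec:
    """One concrete test: four individuals plus a haplotype slot for each."""

    p1: str
    p2: str
    p3: str
    outgroup: str
    haps: tuple[int, int, int, int]
    run: int


# ---------------------------------------------------------------------------
# Site-pattern primitives
# ---------------------------------------------------------------------------

def count_site_patterns(h1, h2, h3, h4) -> tuple[int, int, int]:
    """Count ABBA, BABA and other sites over four aligned haplotype vectors.

    A site counts as ABBA iff h1 == h4 != h2 == h3 and as BABA iff
    h2 == h4 != h1 == h3; both conditions already restrict the site to
    exactly two distinct alleles among the four sequences.  Everything else
    (monomorphic, singleton, three-allele, ...) is "other".
    """
    h1, h2, h3, h4 = (np.asarray(h) for h in (h1, h2, h3, h4))
    if not (h1.shape == h2.shape == h3.shape == h4.shape):
        raise ValueError("haplotype vectors must have equal length")
    abba = (h1 == h4) & (h2 == h3) & (h1 != h2)
    baba = (h1 == h3) & (h2 == h4) & (h1 != h2)
    n_abba = int(abba.sum())
    n_baba = int(baba.sum())
    return n_abba, n_baba, int(h1.size - n_abba - n_baba)


def d_from_counts(n_abba: float, n_baba: float) -> float:
    """Patterson's D = (nABBA - nBABA) / (nABBA + nBABA); NaN if both zero."""
    if n_abba < 0 or n_baba < 0:
        raise ValueError("pattern counts must be non-negative")
    total = n_abba + n_baba
    if total == 0:
        return float("nan")
    return (n_abba - n_baba) / total


# ---------------------------------------------------------------------------
# Test enumeration
# ---------------------------------------------------------------------------

def _hap_assignments(scheme: str) -> list[tuple[int, int, int, int]]:
    if scheme == "paired":
        return [(0, 0, 0, 0), (1, 1, 1, 1)]
    return list(itertools.product((0, 1), repeat=4))


def enumerate_tests(
    pm: PopulationMap, cfg: QuartetConfig, p2_individual: str
) -> list[QuartetSpec]:
    """All quartet tests for one P2 individual.

    The Cartesian product of P1 x P3 x Outgroup reference individuals is
    crossed with the haplotype assignments of the allele scheme.  When the
    P2 individual belongs to a reference group (control tests) it is removed
    from that group's pool, so it never serves as its own reference.
    """
    pools = {}
    for role, group in (("p1", cfg.p1), ("p3", cfg.p3), ("out", cfg.outgroup)):
        members = [i for i in pm.members(group) if i != p2_individual]
        if not members:
            raise ValueError(
                f"reference pool for {role} ({group}) empty after removing {p2_individual}"
            )
        pools[role] = members
    specs = []
    assignments = _hap_assignments(cfg.allele_scheme)
    for i1 in pools["p1"]:
        for i3 in pools["p3"]:
            for i4 in pools["out"]:
                for run, haps in enumerate(assignments):
                    specs.append(QuartetSpec(i1, p2_individual, i3, i4, haps, run))
    return specs


# ---------------------------------------------------------------------------
# Individual-based pipeline
# ---------------------------------------------------------------------------

@dataclass
class DSummary:
    """All per-test results plus per-individual and per-taxon aggregates.

    ``per_test`` has one row per quartet test; ``per_individual`` averages
    over each P2 individual's tests (NaN-D tests excluded, count logged in
    ``n_nan_tests``); ``per_taxon`` averages the member-individual means
    with equal weight.  ``s_max`` is the mean introgression excess over the
    maximal-gene-flow control tests, the denominator of f.
    """

    per_test: pd.DataFrame
    per_individual: pd.DataFrame
    per_taxon: pd.DataFrame
    s_max: float
    n_nan_tests: int
    config: QuartetConfig


def _encode_biallelic(gm: GenotypeMatrix) -> np.ndarray:
    if not gm.biallelic_mask().all() or gm.missing_mask().any():
        raise ValueError("D tests require a complete biallelic matrix")
    return np.ascontiguousarray(gm.calls.transpose(1, 2, 0).astype(np.int8))


def run_individual_dstat(
    gm: GenotypeMatrix, pm: PopulationMap, cfg: QuartetConfig
) -> DSummary:
    """Exhaustive individual-based ABBA/BABA tests with summaries and f.

    Every P2 candidate individual (and, with controls, every P1 and P3
    individual) is tested against all reference combinations under the
    configured allele scheme.
    """
    pm.validate(gm)
    G = _encode_biallelic(gm)  # (N, 2, L)
    ind_index = {ind: i for i, ind in enumerate(gm.individual_ids)}

    p2_plan: list[tuple[str, str, str]] = []  # (group, role, individual)
    for group in cfg.p2_candidates:
        for ind in pm.members(group):
            p2_plan.append((group, ROLE_CANDIDATE, ind))
    if cfg.include_controls:
        for ind in pm.members(cfg.p1):
            p2_plan.append((cfg.p1, ROLE_CONTROL_ZERO, ind))
        for ind in pm.members(cfg.p3):
            p2_plan.append((cfg.p3, ROLE_CONTROL_MAX, ind))

    records = []
    for group, role, p2_ind in p2_plan:
        for spec in enumerate_tests(pm, cfg, p2_ind):
            a = G[ind_index[spec.p1], spec.haps[0]]
            b = G[ind_index[spec.p2], spec.haps[1]]
            c = G[ind_index[spec.p3], spec.haps[2]]
            d = G[ind_index[spec.outgroup], spec.haps[3]]
            diff = a != b
            n_abba = int((diff & (a == d) & (b == c)).sum())
            n_baba = int((diff & (a == c) & (b == d)).sum())
            records.append(
                (
                    group,
                    role,
                    p2_ind,
                    spec.p1,
                    spec.p3,
                    spec.outgroup,
                    spec.run,
                    n_abba,
                    n_baba,
                )
            )
    per_test = pd.DataFrame(
        records,
        columns=[
            "p2_group",
            "role",
            "p2_individual",
            "p1",
            "p3",
            "outgroup",
            "run",
            "nABBA",
            "nBABA",
        ],
    )
    totals = per_test["nABBA"] + per_test["nBABA"]
    with np.errstate(invalid="ignore"):
        per_test["D"] = (per_test["nABBA"] - per_test["nBABA"]) / totals.where(totals > 0)
    per_test["S"] = per_test["nABBA"] - per_test["nBABA"]
    n_nan = int(per_test["D"].isna().sum())
    if n_nan:
        warnings.warn(f"{n_nan} tests had no informative sites (D = NaN), excluded from means")

    per_individual = (
        per_test.groupby(["p2_group", "role", "p2_individual"], sort=False)
        .agg(
            n_tests=("D", "size"),
            D_mean=("D", "mean"),
            D_sd=("D", "std"),
            nABBA_mean=("nABBA", "mean"),
            nABBA_sd=("nABBA", "std"),
            nBABA_mean=("nBABA", "mean"),
            nBABA_sd=("nBABA", "std"),
            S_mean=("S", "mean"),
        )
        .reset_index()
    )

    summary = DSummary(
        per_test=per_test,
        per_individual=per_individual,
        per_taxon=pd.DataFrame(),
        s_max=float("nan"),
        n_nan_tests=n_nan,
        config=cfg,
    )
    if cfg.include_controls:
        admixture_fraction(summary)
    summary.per_taxon = (
        summary.per_individual.groupby(["p2_group", "role"], sort=False)
        .agg(
            n_individuals=("p2_individual", "size"),
            n_tests=("n_tests", "sum"),
            D_mean=("D_mean", "mean"),
            D_sd=("D_mean", "std"),
            nABBA_mean=("nABBA_mean", "mean"),
            nBABA_mean=("nBABA_mean", "mean"),
            **(
                {"f_mean": ("f", "mean"), "f_sd": ("f", "std")}
                if "f" in summary.per_individual
                else {}
            ),
        )
        .reset_index()
    )
    return summary


def admixture_fraction(summary: DSummary) -> pd.DataFrame:
    """Attach the admixture fraction f (percent) to the per-individual table.

    f_i = S_i / S_max where S_i is individual i's mean ABBA-BABA excess and
    S_max the pooled mean excess over all maximal-gene-flow control tests
    (P3 members run as P2 with leave-one-out).  Requires those controls.
    """
    ctrl = summary.per_test[summary.per_test["role"] == ROLE_CONTROL_MAX]
    if ctrl.empty:
        raise ValueError("admixture fraction requires maximal-gene-flow control tests")
    s_max = float(ctrl["S"].mean())
    if s_max <= 0:
        raise ValueError(
            f"mean control introgression excess S_max = {s_max:.3f} <= 0; "
            "the P3 group does not behave as a gene-flow donor here"
        )
    summary.s_max = s_max
    summary.per_individual["f"] = summary.per_individual["S_mean"] / s_max * 100.0
    return summary.per_individual


# ---------------------------------------------------------------------------
# Reference-sample bias
# ---------------------------------------------------------------------------

def reference_bias_analysis(
    per_test: pd.DataFrame,
    roles: tuple[str, ...] = ("p1", "p3", "outgroup"),
    outlier_threshold: float = 0.1,
    method: str = "anova",
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Effect of the choice of reference individual on D.

    Over the candidate (non-control) tests, computes for each reference role
    and each individual serving in it the mean D and its deviation from the
    grand mean, flags |deviation| > ``outlier_threshold``, and tests for a
    global effect of individual identity per role with one-way ANOVA
    (``method="kruskal"`` for the rank-based alternative).  Test-count
    weighted deviations sum to zero within each role by construction.

    The p-values should be read as descriptive, not calibrated: the
    exhaustive enumeration reuses the same loci and the same co-references
    across tests, so D values are strongly dependent, and each individual's
    realized genotype has a genuine systematic effect on D even when
    individuals are exchangeable draws from one population.  The deviation
    magnitudes and the outlier flags are the robust readout; the study-scale
    null distribution of deviations is documented in the methods note.
    """
    cand = per_test[per_test["role"] == ROLE_CANDIDATE].dropna(subset=["D"])
    if cand.empty:
        raise ValueError("no candidate tests with defined D")
    grand = float(cand["D"].mean())
    rows = []
    pvalues: dict[str, float] = {}
    for role in roles:
        per_ref = cand.groupby(role)["D"]
        if per_ref.ngroups < 2:
            warnings.warn(f"role {role}: only one reference individual, skipped")
            continue
        samples = [g.to_numpy() for _, g in per_ref]
        if method == "anova":
            _, p = stats.f_oneway(*samples)
        elif method == "kruskal":
            _, p = stats.kruskal(*samples)
        else:
            raise ValueError(f"unknown method {method!r}")
        pvalues[role] = float(p)
        for ind, g in per_ref:
            dev = float(g.mean()) - grand
            rows.append(
                {
                    "role": role,
                    "individual": ind,
                    "n_tests": int(g.size),
                    "D_mean": float(g.mean()),
                    "deviation": dev,
                    "outlier": abs(dev) > outlier_threshold,
                }
            )
    return pd.DataFrame(rows), pvalues


# ---------------------------------------------------------------------------
# Population-frequency D
# ---------------------------------------------------------------------------

@dataclass
class PopulationDResult:
    """Population-frequency Patterson's D with its ingredients.

    ``freqs`` rows are the derived-allele frequencies p1, p2, p3, p4 per
    locus; ``n_copies`` the gene copies sampled per population (the binomial
    n of the bootstrap).  Bootstrap fields are filled in by
    :func:`bootstrap_population_d`.
    """

    d: float
    freqs: np.ndarray  # (4, L)
    n_copies: np.ndarray  # (4,)
    locus_ids: list[str]
    groups: tuple[str, str, str, str]
    replicates: np.ndarray | None = None
    d_range: tuple[float, float] | None = None
    significant: bool | None = None
    n_reps: int | None = None
    seed: int | None = None


def _pop_d_from_freqs(freqs: np.ndarray) -> float:
    p1, p2, p3, p4 = freqs
    abba = (1 - p1) * p2 * p3 * (1 - p4)
    baba = p1 * (1 - p2) * p3 * (1 - p4)
    denom = (abba + baba).sum()
    if denom == 0:
        warnings.warn("population D denominator is zero")
        return float("nan")
    return float((abba - baba).sum() / denom)


def population_dstat(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    cfg: QuartetConfig,
    p2_group: str,
) -> PopulationDResult:
    """Patterson's D from per-population derived-allele frequencies.

    Per locus the derived allele is the least frequent allele among the
    outgroup gene copies; an exact 0.5 tie is broken by the global minor
    allele, then by lexicographic label order, so polarization is fully
    deterministic.
    """
    pm.validate(gm)
    if not gm.biallelic_mask().all() or gm.missing_mask().any():
        raise ValueError("population D requires a complete biallelic matrix")
    groups = (cfg.p1, p2_group, cfg.p3, cfg.outgroup)
    freq1 = []
    n_copies = []
    for g in groups:
        idx = [gm.individual_index(i) for i in pm.members(g)]
        sub = gm.calls[:, idx, :].reshape(gm.n_loci, -1)
        freq1.append(sub.mean(axis=1))
        n_copies.append(sub.shape[1])
    freq1 = np.stack(freq1)  # frequency of allele code 1
    n_copies = np.array(n_copies)

    out_f1 = freq1[3]
    global_f1 = gm.calls.reshape(gm.n_loci, -1).mean(axis=1)
    labels0 = np.array([lab[0] for lab in gm.allele_labels])
    labels1 = np.array([lab[1] for lab in gm.allele_labels])
    # derived allele: least frequent in outgroup; ties -> global minor -> lexicographic
    derived_is_1 = out_f1 < 0.5
    tie = out_f1 == 0.5
    derived_is_1[tie] = global_f1[tie] < 0.5
    tie2 = tie & (global_f1 == 0.5)
    derived_is_1[tie2] = labels1[tie2] < labels0[tie2]

    freqs = np.where(derived_is_1[None, :], freq1, 1.0 - freq1)
    return PopulationDResult(
        d=_pop_d_from_freqs(freqs),
        freqs=freqs,
        n_copies=n_copies,
        locus_ids=list(gm.locus_ids),
        groups=groups,
    )


def bootstrap_population_d(
    result: PopulationDResult, n_reps: int = 100, seed: int = 0
) -> PopulationDResult:
    """Binomial bootstrap of the population D.

    Per replicate, the derived-allele count of every locus x population cell
    is redrawn from Binomial(n = gene copies sampled, p = observed derived
    frequency) and D recomputed.  The min-max range of replicate D values is
    reported, with significance declared when it excludes zero.
    """
    rng = np.random.default_rng(seed)
    n = result.n_copies[:, None]
    reps = np.empty(n_reps)
    for r in range(n_reps):
        freqs = rng.binomial(n, result.freqs) / n
        reps[r] = _pop_d_from_freqs(freqs)
    result.replicates = reps
    lo, hi = float(np.nanmin(reps)), float(np.nanmax(reps))
    result.d_range = (lo, hi)
    result.significant = bool(lo > 0 or hi < 0)
    result.n_reps = n_reps
    result.seed = seed
    return result
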