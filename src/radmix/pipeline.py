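"""End-to-end orchestration: filter -> diversity -> Fst -> triangle ->
individual D + f + bias -> population D + bootstrap, with every table
written once and all randomness seeded from one master seed.

Each numeric cell of the report comes from exactly one library operation;
the pipeline only sequences the stages and serializes their outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .ancestry import ancestry_table, find_diagnostic_loci, triangle_curves
from .diversity import diversity_table, pairwise_fst
from .dstat import (
    QuartetConfig,
    bootstrap_population_d,
    population_dstat,
    reference_bias_analysis,
    run_individual_dstat,
)
from .genotypes import (
    GenotypeMatrix,
    PopulationMap,
    filter_complete_biallelic,
    read_genotypes,
    read_population_map,
)

logger = logging.getLogger("radmix")

__all__ = ["RunConfig", "run_analysis", "derive_seed"]


def derive_seed(master: int, stage: str) -> int:
    """Stage seed derived from the master seed via numpy's SeedSequence.

    The stage name is hashed into a spawn key, so every stage gets an
    independent, reproducible stream and partial re-runs see the same seeds.
    """
    key = sum(ord(c) * (31**i) for i, c in enumerate(stage)) % (2**31)
    return int(np.random.SeedSequence(entropy=master, spawn_key=(key,)).generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Inputs, role assignments and analysis parameters for one run."""

    genotypes: str
    popmap: str
    p1: str
    p3: str
    outgroup: str
    p2_candidates: list[str] = field(default_factory=list)
    allele_scheme: str = "paired"
    n_perm: int = 1000
    n_reps: int = 100
    rarefaction_n: int | None = None
    seed: int = 1
    outdir: str = "radmix_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate_groups(self, pm: PopulationMap) -> None:
        known = set(pm.groups)
        for g in [self.p1, self.p3, self.outgroup, *self.p2_candidates]:
            if g not in known:
                raise ValueError(f"group {g!r} not present in the population map")


def _stage(name: str, t0: float, **shapes) -> None:
    info = " ".join(f"{k}={v}" for k, v in shapes.items())
    logger.info("stage=%s elapsed=%.2fs %s", name, time.time() - t0, info)


def run_analysis(
    cfg: RunConfig,
    gm: GenotypeMatrix | None = None,
    pm: PopulationMap | None = None,
) -> dict[str, Path]:
    """Run the full analysis and write one TSV per table plus JSON metadata.

    ``gm``/``pm`` may be passed directly (e.g. fresh from the simulator);
    otherwise they are read from the configured paths.  Returns the mapping
    of table name to written path.  Reruns with identical inputs and seeds
    produce identical bytes.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    if gm is None:
        gm = read_genotypes(cfg.genotypes)
    if pm is None:
        pm = read_population_map(cfg.popmap)
    cfg.validate_groups(pm)
    n_input = gm.n_loci
    gm = filter_complete_biallelic(gm)
    _stage("filter", t0, loci_in=n_input, loci_out=gm.n_loci, individuals=gm.n_individuals)

    paths: dict[str, Path] = {}

    div = diversity_table(gm, pm, rarefaction_n=cfg.rarefaction_n)
    paths["diversity"] = outdir / "diversity.tsv"
    div.to_csv(paths["diversity"], sep="\t", float_format="%.6g")
    _stage("diversity", t0, groups=len(div))

    fst_seed = derive_seed(cfg.seed, "fst")
    fst = pairwise_fst(gm, pm, n_perm=cfg.n_perm, seed=fst_seed)
    paths["fst"] = outdir / "fst.tsv"
    with open(paths["fst"], "w") as fh:
        fh.write("# pairwise Weir-Cockerham theta (lower) / permutation p (upper)\n")
        combined = fst.fst.where(
            np.tril(np.ones(fst.fst.shape, bool), k=-1), fst.pvalues
        )
        combined.to_csv(fh, sep="\t", float_format="%.6g")
    _stage("fst", t0, pairs=len(fst.fst) * (len(fst.fst) - 1) // 2)

    panel = find_diagnostic_loci(gm, pm, cfg.p1, cfg.p3)
    anc = ancestry_table(gm, panel) if len(panel) else None
    paths["ancestry"] = outdir / "ancestry.tsv"
    if anc is not None:
        anc.to_csv(paths["ancestry"], sep="\t", float_format="%.6g")
    else:
        paths["ancestry"].write_text("individual\tq\tQ12\tL\n")
    paths["triangle"] = outdir / "triangle_bounds.tsv"
    triangle_curves().to_csv(paths["triangle"], sep="\t", index=False, float_format="%.6g")
    _stage("ancestry", t0, panel_loci=len(panel))

    qcfg = QuartetConfig(
        p1=cfg.p1,
        p3=cfg.p3,
        outgroup=cfg.outgroup,
        p2_candidates=list(cfg.p2_candidates),
        allele_scheme=cfg.allele_scheme,
    )
    summary = run_individual_dstat(gm, pm, qcfg)
    paths["dstat_tests"] = outdir / "dstat_tests.tsv"
    summary.per_test.to_csv(paths["dstat_tests"], sep="\t", index=False, float_format="%.6g")
    paths["dstat_individuals"] = outdir / "dstat_individuals.tsv"
    summary.per_individual.to_csv(
        paths["dstat_individuals"], sep="\t", index=False, float_format="%.6g"
    )
    paths["dstat_summary"] = outdir / "dstat_summary.tsv"
    summary.per_taxon.to_csv(paths["dstat_summary"], sep="\t", index=False, float_format="%.6g")
    _stage("dstat_individual", t0, tests=len(summary.per_test), nan_tests=summary.n_nan_tests)

    bias, bias_p = reference_bias_analysis(summary.per_test)
    paths["reference_bias"] = outdir / "reference_bias.tsv"
    bias.to_csv(paths["reference_bias"], sep="\t", index=False, float_format="%.6g")
    _stage("bias", t0, roles=len(bias_p))

    boot_seed = derive_seed(cfg.seed, "bootstrap")
    pop_rows = []
    for group in cfg.p2_candidates:
        res = population_dstat(gm, pm, qcfg, group)
        res = bootstrap_population_d(res, n_reps=cfg.n_reps, seed=boot_seed)
        pop_rows.append(
            {
                "p2_group": group,
                "D": res.d,
                "D_min": res.d_range[0],
                "D_max": res.d_range[1],
                "significant": res.significant,
                "n_reps": res.n_reps,
            }
        )
    import pandas as pd

    paths["dstat_population"] = outdir / "dstat_population.tsv"
    pd.DataFrame(pop_rows).to_csv(
        paths["dstat_population"], sep="\t", index=False, float_format="%.6g"
    )
    _stage("dstat_population", t0, groups=len(pop_rows))

    from . import __version__ as version

    meta = {
        "radmix_version": version,
        "config": {
            **{k: getattr(cfg, k) for k in ("p1", "p3", "outgroup", "p2_candidates")},
            "allele_scheme": cfg.allele_scheme,
            "n_perm": cfg.n_perm,
            "n_reps": cfg.n_reps,
            "rarefaction_n": cfg.rarefaction_n,
        },
        "seeds": {"master": cfg.seed, "fst": fst_seed, "bootstrap": boot_seed},
        "n_loci_input": n_input,
        "n_loci_complete_biallelic": gm.n_loci,
        "n_individuals": gm.n_individuals,
        "n_diagnostic_loci": len(panel),
        "n_nan_tests": summary.n_nan_tests,
        "bias_pvalues": bias_p,
    }
    paths["metadata"] = outdir / "metadata.json"
    paths["metadata"].write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return paths
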