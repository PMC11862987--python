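"""End-to-end orchestration: simulate -> diversity -> overlap -> cluster -> phylo-D.

One master seed drives every stage; stage seeds are derived by hashing
(master seed, stage name) so the pipeline is reproducible end to end and
stages stay decoupled.  All outputs are plain text (TSV / JSON / Newick)
under one output directory, together with a manifest recording versions,
seeds and input hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clusters import NicheKMeans
from .diversity import PCoA, bray_curtis, diversity_table, rarefy
from .io import (
    read_community,
    read_tree,
    write_gradient_result,
    write_json,
)
from .overlap import NicheOverlapTest
from .phylo import PhyloDTest
from .simulate import (
    CommunityMatrix,
    GuildedTree,
    SimScenario,
    default_scenario,
    generate_guilded_tree,
    simulate_gradient,
)

__all__ = ["RunConfig", "run_all", "stage_seed", "load_config"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "diversity", "overlap", "cluster", "phylod")


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 from the master seed."""
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Configuration for one full pipeline run.

    Provide either input paths (``counts``/``metadata``, optional ``tree``)
    or ``scenario`` for a synthetic run; ``scenario=None`` with no inputs
    falls back to the default synthetic gradient.
    """

    outdir: str | Path = "taunich_run"
    counts: str | None = None
    metadata: str | None = None
    tree: str | None = None
    scenario: SimScenario | None = None
    occupancy_cutoff: float = 0.70
    n_rand: int = 100
    n_perm: int = 1000
    k: int | str = "auto"
    depth: int | str = "auto"
    master_seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts is None) != (self.metadata is None):
            raise ValueError("counts and metadata must be given together")


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from a TOML or YAML file."""
    path = Path(path)
    if path.suffix == ".toml":
        import tomllib

        raw = tomllib.loads(path.read_text())
    elif path.suffix in {".yaml", ".yml"}:
        import yaml

        raw = yaml.safe_load(path.read_text())
    else:
        raise ValueError(f"unsupported config format: {path.suffix}")
    scenario = None
    if "scenario" in raw:
        s = raw.pop("scenario")
        seed = int(s.pop("seed", 0))
        base = default_scenario(seed)
        from dataclasses import replace

        scenario = replace(base, **{k: v for k, v in s.items()})
    known = {f for f in RunConfig.__dataclass_fields__ if f != "extra"}
    cfg = {k: v for k, v in raw.items() if k in known}
    extra = {k: v for k, v in raw.items() if k not in known}
    return RunConfig(scenario=scenario, extra=extra, **cfg)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage and write all outputs plus a manifest.

    Returns a result bundle (stage name -> in-memory result).  A missing tree
    skips the phylo-D stage with a warning; any other stage failure aborts
    with the failing stage named, keeping partial outputs on disk.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "taunich_version": __version__,
        "master_seed": cfg.master_seed,
        "stage_seeds": {s: stage_seed(cfg.master_seed, s) for s in STAGES},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "inputs": {},
        "stages": {},
    }
    bundle: dict = {}
    stage = "setup"
    try:
        # ------------------------------------------------ inputs / simulate
        tree = None
        guilded: GuildedTree | None = None
        if cfg.counts is not None:
            stage = "load"
            community = read_community(cfg.counts, cfg.metadata)
            manifest["inputs"]["counts"] = _sha256(Path(cfg.counts))
            manifest["inputs"]["metadata"] = _sha256(Path(cfg.metadata))
            if cfg.tree:
                tree = read_tree(cfg.tree)
                manifest["inputs"]["tree"] = _sha256(Path(cfg.tree))
        else:
            stage = "simulate"
            from dataclasses import replace

            scenario = cfg.scenario or default_scenario(
                stage_seed(cfg.master_seed, "simulate")
            )
            if cfg.scenario is not None:
                scenario = replace(
                    scenario, seed=stage_seed(cfg.master_seed, "simulate")
                )
            sim = simulate_gradient(scenario)
            bundle["simulate"] = sim
            community = sim.community
            guilded = generate_guilded_tree(
                guild_truth=sim.guild_truth,
                clustering_strength=3.0,
                seed=stage_seed(cfg.master_seed, "simulate"),
            )
            tree = guilded.tree
            write_gradient_result(sim, outdir, tree=guilded)
            manifest["stages"]["simulate"] = {
                "n_taxa": scenario.n_taxa,
                "n_chemostats": len(scenario.tau_grid),
                "read_depth": scenario.read_depth,
            }
        bundle["community"] = community

        # ------------------------------------------------ diversity
        stage = "diversity"
        seed_div = stage_seed(cfg.master_seed, "diversity")
        depth = None if cfg.depth == "auto" else int(cfg.depth)
        div = diversity_table(
            community.counts, community.tau, depth=depth, seed=seed_div
        )
        div.to_csv(outdir / "diversity.tsv", sep="\t")
        rar = rarefy(community.counts, depth=depth, seed=seed_div)
        bc = bray_curtis(rar.counts)
        ord_est = PCoA().fit(bc)
        coords = ord_est.coordinates_.copy()
        coords.insert(0, "tau_hours", community.tau.to_numpy())
        coords.to_csv(outdir / "ordination.tsv", sep="\t", index_label="chemostat")
        bundle["diversity"] = div
        bundle["ordination"] = ord_est
        manifest["stages"]["diversity"] = {
            "depth": rar.depth,
            "pcoa_var_explained_axis1": float(ord_est.variance_explained_[0]),
        }

        # ------------------------------------------------ niche overlap
        stage = "overlap"
        ot = NicheOverlapTest(
            cutoff=cfg.occupancy_cutoff,
            n_rand=cfg.n_rand,
            seed=stage_seed(cfg.master_seed, "overlap"),
        ).fit(community)
        bundle["overlap"] = ot.result_
        overlap_json = {
            "observed_mean": ot.observed_mean_,
            "nulls": ot.result_.null_summary,
            "n_taxa_used": ot.n_taxa_used_,
            "occupancy_cutoff": cfg.occupancy_cutoff,
            "seed": ot.seed,
        }
        write_json(overlap_json, outdir / "overlap.json")
        manifest["stages"]["overlap"] = {
            "observed_mean": ot.observed_mean_,
            "p": ot.p_value_,
        }

        # ------------------------------------------------ niche clustering
        stage = "cluster"
        km = NicheKMeans(
            k=cfg.k,
            cutoff=cfg.occupancy_cutoff,
            random_state=stage_seed(cfg.master_seed, "cluster"),
        ).fit(community)
        assign = km.assignment_
        km.labels_.rename("niche").rename_axis("taxon").reset_index().to_csv(
            outdir / "niche_labels.tsv", sep="\t", index=False
        )
        pd.Series(km.wss_by_k_, name="wss").rename_axis("k").reset_index().to_csv(
            outdir / "wss.tsv", sep="\t", index=False
        )
        prof_long = (
            assign.niche_profile.T.rename_axis("chemostat")
            .assign(tau_hours=community.tau)
            .reset_index()
            .melt(
                id_vars=["chemostat", "tau_hours"],
                var_name="niche",
                value_name="combined_rel_abund",
            )
        )
        prof_long.to_csv(outdir / "niche_profiles.tsv", sep="\t", index=False)
        write_json(
            {"k": km.k_, "niche_share": assign.niche_share.to_dict()},
            outdir / "niche_summary.json",
        )
        bundle["cluster"] = km
        manifest["stages"]["cluster"] = {
            "k": km.k_,
            "n_taxa_clustered": len(km.kept_taxa_),
        }

        # ------------------------------------------------ phylogenetic D
        stage = "phylod"
        if tree is None:
            logger.warning("no tree provided: skipping phylogenetic dispersion")
            manifest["stages"]["phylod"] = "skipped (no tree)"
        else:
            tip_names = {
                lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon
            }
            phylod: dict[str, dict] = {}
            # the two major niches = largest combined relative abundance
            major = assign.niche_share.sort_values(ascending=False).index[:2]
            for niche in major:
                members = set(
                    km.labels_.index[km.labels_ == niche]
                ) & tip_names
                states = {t: int(t in members) for t in tip_names}
                if not 0 < sum(states.values()) < len(states):
                    logger.warning(
                        "niche %s trivial on the tree; skipping", niche
                    )
                    continue
                pe = PhyloDTest(
                    n_perm=cfg.n_perm,
                    seed=stage_seed(cfg.master_seed, "phylod"),
                ).fit(tree, states)
                phylod[str(niche)] = {
                    "d_obs": pe.d_obs_,
                    "D": pe.D_,
                    "p_random": pe.p_random_,
                    "p_brownian": pe.p_brownian_,
                    "cohens_d": pe.cohens_d_,
                    "n_perm": cfg.n_perm,
                    "seed": pe.seed,
                }
            write_json(phylod, outdir / "phylod.json")
            bundle["phylod"] = phylod
            manifest["stages"]["phylod"] = {
                n: {"D": v["D"], "p_random": v["p_random"]}
                for n, v in phylod.items()
            }
    except Exception as exc:  # noqa: BLE001 - abort names the failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    write_json(manifest, outdir / "manifest.json")
    bundle["manifest"] = manifest
    return bundle
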