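"""Reading and writing the pipeline's plain-text formats.

Counts are TSV with taxa as rows and chemostats as columns; metadata is a
two-column TSV (chemostat_id, tau_hours); trees are Newick; ground truth and
stage summaries are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import dendropy
import pandas as pd

from .rates import EcoPlateReading
from .simulate import CommunityMatrix, GradientResult, GuildedTree

__all__ = [
    "read_counts",
    "read_metadata",
    "read_community",
    "write_community",
    "read_ecoplate",
    "read_tree",
    "write_tree",
    "write_gradient_result",
    "write_json",
]


def read_ecoplate(path: str | Path, blank_column: str = "blank") -> EcoPlateReading:
    """Read an EcoPlate TSV: substrate rows, replicate OD columns + one blank.

    The blank column holds the water-blank OD590 (constant or per-replicate
    is a scoring-time concern; here one value per substrate row is averaged).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if blank_column not in df.columns:
        raise ValueError(f"{path}: missing blank column {blank_column!r}")
    blank = float(df[blank_column].mean())
    return EcoPlateReading(
        od_by_substrate=df.drop(columns=[blank_column]), blank_od=blank
    )


def read_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValueError(f"{path}: empty counts table")
    return df


def read_metadata(path: str | Path) -> pd.Series:
    meta = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in meta.columns}
    if "chemostat_id" not in cols or "tau_hours" not in cols:
        raise ValueError(
            f"{path}: metadata needs 'chemostat_id' and 'tau_hours' columns"
        )
    tau = meta.set_index(cols["chemostat_id"])[cols["tau_hours"]]
    tau.name = "tau_hours"
    return tau


def read_community(
    counts_path: str | Path, meta_path: str | Path
) -> CommunityMatrix:
    counts = read_counts(counts_path)
    tau = read_metadata(meta_path)
    missing = [c for c in counts.columns if c not in tau.index]
    if missing:
        raise ValueError(f"metadata missing chemostats: {missing}")
    return CommunityMatrix(counts=counts, tau=tau.loc[counts.columns])


def write_community(cm: CommunityMatrix, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cm.counts.to_csv(outdir / "counts.tsv", sep="\t", index_label="taxon_id")
    meta = cm.tau.rename_axis("chemostat_id").reset_index()
    meta.to_csv(outdir / "metadata.tsv", sep="\t", index=False)


def read_tree(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_tree(tree: GuildedTree | dendropy.Tree, path: str | Path) -> None:
    t = tree.tree if isinstance(tree, GuildedTree) else tree
    t.write(path=str(path), schema="newick", suppress_rooting=True)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def _jsonable(x):
    try:
        return x.item()  # numpy scalars
    except AttributeError:
        return str(x)


def write_gradient_result(
    result: GradientResult, outdir: str | Path, tree: GuildedTree | None = None
) -> None:
    """Write counts, metadata, ground truth (and optionally the tree)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_community(result.community, outdir)
    truth = {
        "guild_of_taxon": result.guild_truth.to_dict(),
        "seed": result.scenario.seed,
        "read_depth": result.scenario.read_depth,
        "tau_hours": [float(t) for t in result.scenario.tau_grid],
    }
    write_json(truth, outdir / "ground_truth.json")
    if tree is not None:
        write_tree(tree, outdir / "tree.nwk")
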