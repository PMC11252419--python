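"""Readers/writers for the formats the tool exchanges with the outside world:
delimited count tables, h5ad single-cell containers, GMT gene-set
collections, and JSON cohort-state manifests."""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "read_bulk_counts",
    "read_gmt",
    "write_gmt",
    "write_cohort",
    "load_state_json",
    "dump_state_json",
]


def read_bulk_counts(path) -> tuple[np.ndarray, list, list]:
    """Read a samples x genes count table from TSV/CSV or h5ad.

    Returns ``(counts, sample_ids, gene_ids)``.
    """
    path = Path(path)
    if path.suffix == ".h5ad":
        adata = ad.read_h5ad(path)
        X = np.asarray(adata.X.todense() if hasattr(adata.X, "todense") else adata.X)
        return X, list(adata.obs_names), list(adata.var_names)
    sep = "," if path.suffix == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    return df.to_numpy(dtype=float), list(df.index), list(df.columns)


def read_gmt(path) -> dict:
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise DataError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict, path) -> None:
    lines = [f"{name}\tsemiprofile\t" + "\t".join(members)
             for name, members in sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def write_cohort(cohort, outdir) -> None:
    """Write a synthetic cohort: per-sample h5ad, ground truth TSV, bulk TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, sid in enumerate(cohort.sample_ids):
        adata = ad.AnnData(
            X=np.asarray(cohort.cell_matrices[i], dtype=np.float32),
            obs=pd.DataFrame({"cell_type": cohort.cell_labels[i]},
                             index=[f"{sid}_c{j}" for j in
                                    range(len(cohort.cell_labels[i]))]),
            var=pd.DataFrame(index=cohort.gene_ids),
        )
        adata.write_h5ad(outdir / f"{sid}.h5ad")
    rows = [
        {"sample": sid, "cell_type": t, "proportion": cohort.true_proportions[i, t]}
        for i, sid in enumerate(cohort.sample_ids)
        for t in range(cohort.true_proportions.shape[1])
    ]
    pd.DataFrame(rows).to_csv(outdir / "true_proportions.tsv", sep="\t", index=False)
    for name in ("pseudobulk", "real_bulk"):
        pd.DataFrame(getattr(cohort, name), index=cohort.sample_ids,
                     columns=cohort.gene_ids).to_csv(
            outdir / f"{name}.tsv", sep="\t")


def dump_state_json(state, path) -> None:
    payload = {
        "representatives": list(state.representatives),
        "assignment": dict(state.assignment),
        "batch_size": state.batch_size,
        "round": state.round,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_state_json(path):
    from .bulk import CohortState

    payload = json.loads(Path(path).read_text())
    return CohortState(
        representatives=list(payload["representatives"]),
        assignment=dict(payload["assignment"]),
        batch_size=int(payload["batch_size"]),
        round=int(payload["round"]),
    )
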