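"""Serialization: RDM CSVs, behavior stacks, result bundles with manifests.

CSV dialect is pinned (UTF-8, comma separator, dot decimal) so round trips are
bit-exact across platforms.  RDMs are written as square CSVs with a header
row/column of stimulus ids and empty diagonal cells; behavior stacks as
long-format CSV (participant, row_item, col_item, value).  Result bundles are
directories of deterministic file names plus a ``manifest.json`` listing every
artifact with its SHA-256 content hash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .rdm import RDM
from .stats import BehaviorRDMStack

__all__ = [
    "RunConfig",
    "rdm_to_csv",
    "rdm_from_csv",
    "write_behavior_rdms",
    "read_behavior_rdms",
    "write_result_bundle",
]

ASYMMETRY_TOL = 1e-9


@dataclass
class RunConfig:
    """Resolved configuration written beside every run's outputs."""

    seed: int = 0
    n_iter: int = 1000
    metric: str = "correlation"
    stratified: bool = False
    inputs: dict = field(default_factory=dict)
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be at least 1")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))

    def write(self, out_dir) -> Path:
        path = Path(out_dir) / "config.json"
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True))
        return path


def rdm_to_csv(rdm: RDM, path) -> None:
    df = pd.DataFrame(rdm.values, index=rdm.stimulus_ids, columns=rdm.stimulus_ids)
    df.to_csv(path, float_format="%.17g", encoding="utf-8")


def rdm_from_csv(path, metric: str = "correlation", strata=None) -> RDM:
    df = pd.read_csv(path, index_col=0, encoding="utf-8")
    return RDM(
        values=df.to_numpy(dtype=float),
        stimulus_ids=[str(c) for c in df.columns],
        metric=metric,
        strata=strata,
    )


def write_behavior_rdms(stack: BehaviorRDMStack, path) -> None:
    """Long-format CSV: participant, row_item, col_item, value (upper triangle)."""
    rows = []
    ids = stack.stimulus_ids
    iu = np.triu_indices(len(ids), k=1)
    for p, rdm in enumerate(stack.rdms):
        for i, j in zip(*iu):
            rows.append((f"p{p:02d}", ids[i], ids[j], rdm.values[i, j]))
    pd.DataFrame(rows, columns=["participant", "row_item", "col_item", "value"]).to_csv(
        path, index=False, float_format="%.17g", encoding="utf-8"
    )


def read_behavior_rdms(path) -> BehaviorRDMStack:
    """Read a long-format behavior CSV into a validated RDM stack.

    Either triangle (or both) may be present; if both, they must agree to
    1e-9.  A missing diagonal is expected; a missing off-diagonal pair is an
    error listing the pairs.
    """
    df = pd.read_csv(path, encoding="utf-8")
    required = {"participant", "row_item", "col_item", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"behavior CSV must have columns {sorted(required)}")
    ids = sorted(set(df["row_item"].astype(str)) | set(df["col_item"].astype(str)))
    index = {s: i for i, s in enumerate(ids)}
    n = len(ids)
    rdms = []
    for participant, grp in df.groupby("participant", sort=True):
        vals = np.full((n, n), np.nan)
        for _, row in grp.iterrows():
            i, j = index[str(row["row_item"])], index[str(row["col_item"])]
            if i == j:
                continue
            v = float(row["value"])
            if not np.isnan(vals[i, j]) and abs(vals[i, j] - v) > ASYMMETRY_TOL:
                raise ValueError(
                    f"asymmetric entries for pair ({ids[i]}, {ids[j]}) "
                    f"of participant {participant}: {vals[i, j]} vs {v}"
                )
            vals[i, j] = v
            vals[j, i] = v
        iu = np.triu_indices(n, k=1)
        missing = [
            (ids[a], ids[b]) for a, b in zip(*iu) if np.isnan(vals[a, b])
        ]
        if missing:
            raise ValueError(
                f"participant {participant} is missing pairs: {missing[:10]}"
            )
        rdms.append(RDM(values=vals, stimulus_ids=ids))
    return BehaviorRDMStack(rdms=rdms)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_result_bundle(results: dict, out_dir) -> dict:
    """Write a result dictionary to a directory and return its manifest.

    Values that are DataFrames become CSVs, dicts/lists become JSON, numpy
    arrays become CSVs.  The manifest lists every file written with its
    SHA-256 hash, so identical configurations yield hash-identical bundles.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(results):
        value = results[name]
        if isinstance(value, pd.DataFrame):
            path = out / f"{name}.csv"
            value.to_csv(path, index=False, float_format="%.17g", encoding="utf-8")
        elif isinstance(value, np.ndarray):
            path = out / f"{name}.csv"
            pd.DataFrame(value).to_csv(
                path, index=False, float_format="%.17g", encoding="utf-8"
            )
        else:
            path = out / f"{name}.json"
            path.write_text(json.dumps(value, indent=2, sort_keys=True, default=str))
        written.append(path)
    manifest = {
        "artifacts": {p.name: _sha256(p) for p in written},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
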