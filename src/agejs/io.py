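"""Readers and writers for capture data, configurations and posterior draws.

Encounter histories travel as a CSV with header ``id,occ1..occK`` and binary
cells; ages as ``id,occasion,age`` with blank cells meaning missing.  Draws
are written one CSV per chain (a column per scalar quantity, a row per
retained draw) next to a JSON run manifest.  Configurations are YAML (or
JSON — YAML is a superset here).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import CaptureData, StudyDesign, ValidationError
from .sampler import MCMCConfig, PosteriorDraws
from .simulate import SimConfig, SimTruth, _config_to_dict, config_from_dict


# ---------------------------------------------------------------------------
# capture data
# ---------------------------------------------------------------------------


def read_capture_data(
    encounters_path: str | Path,
    ages_path: str | Path | None,
    design: StudyDesign | None = None,
) -> CaptureData:
    """Load and validate an encounter CSV plus an optional ages CSV."""
    enc = pd.read_csv(encounters_path, dtype=str).fillna("")
    if enc.columns[0] != "id":
        raise ValidationError("encounter CSV must start with an 'id' column")
    occ_cols = list(enc.columns[1:])
    ids = enc["id"].tolist()
    if len(set(ids)) != len(ids):
        dup = pd.Series(ids)[pd.Series(ids).duplicated()].iloc[0]
        raise ValidationError(f"duplicate id {dup!r} in encounter CSV")
    y = np.zeros((len(ids), len(occ_cols)), dtype=np.int8)
    for j, col in enumerate(occ_cols):
        for i, cell in enumerate(enc[col]):
            if cell not in ("0", "1"):
                raise ValidationError(
                    f"non-binary cell {cell!r} at row {i + 2}, column {col!r}"
                )
            y[i, j] = int(cell)

    n = len(ids)
    age_occ = np.full(n, -1, dtype=np.int64)
    age_val = np.full(n, -1, dtype=np.int64)
    if ages_path is not None:
        ages = pd.read_csv(ages_path, dtype=str).fillna("")
        required = {"id", "occasion", "age"}
        if not required.issubset(ages.columns):
            raise ValidationError("ages CSV needs columns id, occasion, age")
        index = {ind: i for i, ind in enumerate(ids)}
        for r, row in ages.iterrows():
            if row["id"] not in index:
                raise ValidationError(
                    f"ages CSV row {r + 2}: id {row['id']!r} not in encounter CSV"
                )
            if row["age"] == "" or row["occasion"] == "":
                continue
            i = index[row["id"]]
            age_occ[i] = int(row["occasion"])
            age_val[i] = int(row["age"])

    data = CaptureData(ids=ids, y=y, age_occasion=age_occ, age_value=age_val)
    if design is not None:
        data.validate_against(design)
    return data


def write_capture_data(
    data: CaptureData, encounters_path: str | Path, ages_path: str | Path
) -> None:
    K = data.K
    enc = pd.DataFrame(data.y, columns=[f"occ{k + 1}" for k in range(K)])
    enc.insert(0, "id", data.ids)
    enc.to_csv(encounters_path, index=False)
    ages = pd.DataFrame(
        {
            "id": data.ids,
            "occasion": [o if o >= 0 else "" for o in data.age_occasion],
            "age": [a if a >= 0 else "" for a in data.age_value],
        }
    )
    ages.to_csv(ages_path, index=False)


def reformat_case_study(
    txt_path: str | Path,
    encounters_out: str | Path,
    ages_out: str | Path,
    n_occasions: int | None = None,
) -> CaptureData:
    """One-step reformatter from a raw whitespace/comma table to the CSV pair.

    Expects one row per individual: an id column, K binary detection
    columns, and optionally trailing ``age`` and ``age_occasion`` columns
    (blank/NA = unknown age).  A header row is detected and honoured if the
    first field is non-numeric and equals 'id'.
    """
    raw = pd.read_csv(txt_path, sep=None, engine="python", dtype=str).fillna("")
    cols = [c.lower() for c in raw.columns]
    has_age = "age" in cols
    occ_cols = [c for c in raw.columns
                if c.lower() not in ("id", "age", "age_occasion", "occasion")]
    if n_occasions is not None:
        occ_cols = occ_cols[:n_occasions]
    ids = raw[raw.columns[0]].tolist() if cols[0] == "id" else [
        f"ind{i + 1}" for i in range(len(raw))
    ]
    y = raw[occ_cols].replace("", "0").astype(int).to_numpy(dtype=np.int8)
    n = len(ids)
    age_occ = np.full(n, -1, dtype=np.int64)
    age_val = np.full(n, -1, dtype=np.int64)
    if has_age:
        first_det = np.argmax(y == 1, axis=1) + 1
        for i, cell in enumerate(raw[raw.columns[cols.index("age")]]):
            if cell not in ("", "NA", "na"):
                age_val[i] = int(float(cell))
                age_occ[i] = first_det[i]
        if "age_occasion" in cols:
            col = raw[raw.columns[cols.index("age_occasion")]]
            for i, cell in enumerate(col):
                if cell not in ("", "NA", "na"):
                    age_occ[i] = int(float(cell))
    data = CaptureData(ids=ids, y=y, age_occasion=age_occ, age_value=age_val)
    write_capture_data(data, encounters_out, ages_out)
    return data


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def read_sim_config(path: str | Path) -> SimConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def write_sim_config(cfg: SimConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_config_to_dict(cfg), fh)


def read_mcmc_config(path: str | Path) -> MCMCConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if "step_alpha" in d:
        d["step_alpha"] = tuple(d["step_alpha"])
    return MCMCConfig(**d)


def write_truth(truth: SimTruth, path: str | Path) -> None:
    Path(path).write_text(truth.to_json())


# ---------------------------------------------------------------------------
# posterior draws
# ---------------------------------------------------------------------------


def _chain_frame(post: PosteriorDraws, chain: int) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {}
    for name, arr in post.draws.items():
        a = arr[chain]
        if a.ndim == 1:
            cols[name] = a
        elif a.ndim == 2:
            for j in range(a.shape[1]):
                cols[f"{name}_{j + 1}"] = a[:, j]
        elif a.ndim == 3:  # Nkj: occasion x age
            for k in range(a.shape[1]):
                for j in range(a.shape[2]):
                    if arr[:, :, k, j].any():
                        cols[f"{name}_{k + 1}_{j}"] = a[:, k, j]
    return pd.DataFrame(cols)


def write_draws(post: PosteriorDraws, out_dir: str | Path, manifest: dict | None = None) -> None:
    """One CSV per chain plus a JSON run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for chain in range(post.n_chains):
        _chain_frame(post, chain).to_csv(out / f"chain{chain + 1}.csv", index=False)
    meta = {
        "model": post.model,
        "design": {"K": post.design.K, "J": post.design.J,
                   "entry_age": post.design.entry_age, "M": post.design.M},
        "mcmc": {"n_chains": post.mcmc.n_chains, "n_iter": post.mcmc.n_iter,
                 "n_burnin": post.mcmc.n_burnin, "thin": post.mcmc.thin,
                 "seed": post.mcmc.seed},
        "acceptance": post.acceptance,
    }
    if manifest:
        meta.update(manifest)
    meta["config_hash"] = hashlib.sha256(
        json.dumps(meta, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    (out / "manifest.json").write_text(json.dumps(meta, indent=2, default=str))


def read_draws(out_dir: str | Path) -> tuple[list[pd.DataFrame], dict]:
    """Read back per-chain draw CSVs and the manifest."""
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    frames = [
        pd.read_csv(p) for p in sorted(out.glob("chain*.csv"),
                                       key=lambda p: int(p.stem[5:]))
    ]
    return frames, manifest
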