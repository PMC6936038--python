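"""Persistence of ensembles and forecasts as auditable text files.

An ensemble is stored as a CSV table (one row per thinned sample; shape
coefficients in columns c0..c19) plus a JSON metadata sidecar (ζ, seed,
fingerprints, diagnostics).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .geometry import N_COEFFS
from .sampler import HomeostaticEnsemble


def save_ensemble(ens: HomeostaticEnsemble, path: str) -> None:
    path = Path(path)
    df = ens.samples.copy()
    if ens.coefficients is not None:
        for k in range(N_COEFFS):
            df[f"c{k}"] = ens.coefficients[:, k]
    df.to_csv(path, index=False, float_format="%.12g")
    meta = {
        "zeta": ens.zeta,
        "G_S": ens.G_S,
        "seed": ens.seed,
        "diagnostics": _jsonable(ens.diagnostics),
        "params_fingerprint": ens.params_fingerprint,
        "env_fingerprint": ens.env_fingerprint,
        "n_samples": ens.n_samples,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True))


def load_ensemble(path: str) -> HomeostaticEnsemble:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
    coef_cols = [f"c{k}" for k in range(N_COEFFS)]
    coefficients: Optional[np.ndarray] = None
    if all(c in df.columns for c in coef_cols):
        coefficients = df[coef_cols].to_numpy(float)
        df = df.drop(columns=coef_cols)
    return HomeostaticEnsemble(
        zeta=float(meta["zeta"]), samples=df, G_S=float(meta["G_S"]),
        seed=int(meta["seed"]), diagnostics=meta.get("diagnostics", {}),
        coefficients=coefficients,
        params_fingerprint=meta.get("params_fingerprint", ""),
        env_fingerprint=meta.get("env_fingerprint", ""))


def export_traction_grid(shape, model, path: str, um_per_px: float = 1.0,
                         half_extent: float = None) -> None:
    """Export the traction magnitude field as a dense regular grid.

    Writes ``<path>.npy`` (float array, kPa, row order top = +y) plus a JSON
    sidecar ``<path>.json`` with the grid metadata (µm per pixel, origin at
    the grid centre, array shape).
    """
    import numpy as _np
    from .geometry import evaluate_kinematics

    p = model.params
    if half_extent is None:
        half_extent = 3.0 * p.R0
        if model.env.kind == "rigid_island":
            half_extent = max(half_extent, 0.75 * model.env.island_side)
    npx = int(_np.ceil(2 * half_extent / um_per_px))
    bd = model.gibbs(shape, store_tractions=True)
    x = model.disc.positions(shape.coefficients)
    fields = evaluate_kinematics(shape, model.disc)
    w = model.disc.w * fields.J
    tmag = _np.hypot(bd.tractions[:, 0], bd.tractions[:, 1])
    rng = [[-half_extent, half_extent]] * 2
    h, _, _ = _np.histogram2d(x[:, 1], x[:, 0], bins=npx, range=rng,
                              weights=tmag * w)
    a, _, _ = _np.histogram2d(x[:, 1], x[:, 0], bins=npx, range=rng, weights=w)
    grid = _np.zeros_like(h)
    _np.divide(h, a, out=grid, where=a > 0)
    grid = grid[::-1]
    base = Path(path)
    _np.save(base.with_suffix(".npy"), grid)
    base.with_suffix(".json").write_text(json.dumps({
        "um_per_px": um_per_px,
        "origin_um": [0.0, 0.0],
        "half_extent_um": half_extent,
        "shape": list(grid.shape),
        "units": "kPa",
    }, indent=2))


def _jsonable(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, (np.floating, np.integer)):
            v = v.item()
        out[k] = v
    return out
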