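"""Tabular/JSON writers and the run manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import EquilibriumReport
from .simulate import SimResult

__all__ = ["write_tables", "equilibria_to_dict", "sha256_file"]


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def equilibria_to_dict(report: EquilibriumReport, cells=None) -> dict:
    return {
        "regime": report.regime,
        "baseline_index": report.fixed_points.index(report.baseline),
        "fixed_points": [
            {
                "V": [float(v) for v in fp.V],
                "gains": [float(g) for g in fp.gains],
                "stability": fp.stability,
                "method": fp.method,
                "max_eig_real": float(np.max(fp.eigenvalues.real)),
            }
            for fp in report.fixed_points
        ],
        "cells": [c.label for c in cells] if cells else None,
    }


def write_tables(results: dict, out_dir, config_snapshot: dict | None = None,
                 seed: int | None = None, stride: int = 1) -> dict:
    """Write the standard output files and a manifest with checksums.

    ``results`` may contain ``timeseries`` (SimResult), ``sweep``
    (DataFrame) and/or ``equilibria`` (EquilibriumReport); at least one is
    required.  Returns the manifest dict (also written as manifest.json).
    """
    if not results:
        raise ValueError("results is empty: nothing to write")
    known = {"timeseries", "sweep", "equilibria"}
    unknown = set(results) - known
    if unknown:
        raise ValueError(f"unknown result kind {sorted(unknown)[0]!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    if "timeseries" in results:
        res: SimResult = results["timeseries"]
        path = out / "timeseries.csv"
        res.to_dataframe(stride=stride).to_csv(path, index=False, float_format="%.10g")
        written.append(path)
    if "sweep" in results:
        df: pd.DataFrame = results["sweep"]
        path = out / "sweep_summary.csv"
        cols = ["param", "value", "regime", "baseline",
                "short_maintained", "long_maintained", "transient_peak"]
        df.to_csv(path, index=False, columns=[c for c in cols if c in df.columns],
                  float_format="%.10g")
        written.append(path)
    if "equilibria" in results:
        rep: EquilibriumReport = results["equilibria"]
        path = out / "equilibria.json"
        with open(path, "w") as fh:
            json.dump(equilibria_to_dict(rep), fh, indent=2)
        written.append(path)

    from . import __version__
    manifest = {
        "package": "canoncircuit",
        "version": __version__,
        "seed": seed,
        "stride": stride,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "config": config_snapshot,
        "outputs": {p.name: sha256_file(p) for p in written},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
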