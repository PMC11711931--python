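"""Tabular output: TSV files with '#'-prefixed provenance headers.

Every table embeds the resolved configuration and seeds in comment
lines, so any run can be re-derived from its output file alone.
"""

from __future__ import annotations

from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd

from .model_core import ModelParams
from .simulator import RunRecord

__all__ = ["write_run_table", "write_locus_table", "read_table"]


def _version() -> str:
    try:
        return version("chemevol")
    except PackageNotFoundError:
        return "unknown"


def _header_lines(meta: dict) -> list[str]:
    lines = [f"# chemevol {_version()}"]
    for key, value in meta.items():
        if isinstance(value, ModelParams):
            for f in ("N", "theta", "nh", "g", "L", "c", "u"):
                lines.append(f"# {f} = {getattr(value, f)}")
            lines.append(f"# p = {np.asarray(value.p).tolist()}")
            lines.append(f"# da = {value.dom.da.tolist()}")
            lines.append(f"# dc = {value.dom.dc.tolist()}")
            for i, bp in enumerate(value.benefit):
                lines.append(f"# benefit[{i}] = b0={bp.b0} ahalf={bp.ahalf} s={bp.s}")
            lines.append(f"# M = {value.M.tolist()}")
        else:
            lines.append(f"# {key} = {value}")
    return lines


def write_run_table(table: RunRecord | pd.DataFrame, path: str | Path,
                    **meta) -> Path:
    """Write a run record or sweep table as TSV with a provenance header."""
    path = Path(path)
    if isinstance(table, RunRecord):
        if table.params is not None:
            meta.setdefault("params", table.params)
        if table.seed is not None:
            meta.setdefault("seed", table.seed)
        df = table.to_frame()
    else:
        df = table
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("\n".join(_header_lines(meta)) + "\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def write_locus_table(record: RunRecord, path: str | Path, **meta) -> Path:
    """Per-locus final table: effects, dominance, and final allele frequency.

    Supports downstream effect-size-vs-frequency analyses.
    """
    params = record.params
    if params is None:
        raise ValueError("run record carries no parameters")
    final_pi = record.pi[-1]
    data = {"locus": np.arange(1, params.L + 1)}
    for i in range(params.nh):
        data[f"m_{i + 1}"] = params.M[:, i]
    data["da"] = params.dom.da
    data["dc"] = params.dom.dc
    data["final_pi"] = final_pi
    return write_run_table(pd.DataFrame(data), path, params=params,
                           seed=record.seed, **meta)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_run_table` (header skipped)."""
    return pd.read_csv(path, sep="\t", comment="#")
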