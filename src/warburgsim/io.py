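"""Result serialization: tidy CSV tables plus a JSON metadata block.

CSV output is RFC-4180 with '.' decimal separator and 17-significant-digit
floats, so re-reading a table (with round-trip float parsing) reproduces the
in-memory values exactly and re-running a deterministic computation produces
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .steady_state import SteadyStateResult

__all__ = ["write_results", "steady_state_frame", "write_metadata"]


def steady_state_frame(res: SteadyStateResult) -> pd.DataFrame:
    """One row per readout (long form) for a single steady state."""
    rows = [{"readout": k, "value": v, "converged": res.converged,
             "bounded": res.bounded}
            for k, v in res.readouts.as_dict().items()]
    return pd.DataFrame(rows)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    # 17 significant digits round-trip every double exactly
    df.to_csv(path, index=False, float_format=lambda x: format(x, ".17g"),
              lineterminator="\n")


def write_metadata(out_dir: Path, p=None, opts=None, extra: dict | None = None) -> Path:
    from . import __version__
    meta: dict = {
        "package": "warburgsim",
        "version": __version__,
        "deterministic": True,
        "note": "identical configuration reproduces byte-identical outputs",
    }
    if p is not None:
        meta["parameter_hash"] = p.param_hash()
    if opts is not None:
        meta["solver_options"] = {
            "abs_tol": opts.abs_tol, "rel_tol": opts.rel_tol,
            "ss_tol": opts.ss_tol, "t_max": opts.t_max,
            "bound_cap": opts.bound_cap, "max_nfev": opts.max_nfev,
        }
    if extra:
        meta.update(extra)
    path = out_dir / "metadata.json"
    path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return path


def write_results(results, out_dir: str | Path, p=None, opts=None,
                  extra_metadata: dict | None = None) -> list[Path]:
    """Write tidy CSV table(s) plus metadata.json into ``out_dir``.

    ``results`` may be a SteadyStateResult, a SweepResult, a PresetResult or
    a mapping of table name -> DataFrame.  Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    tables: dict[str, pd.DataFrame]
    extra = dict(extra_metadata or {})
    if isinstance(results, SteadyStateResult):
        tables = {"steady_state": steady_state_frame(results),
                  "state": pd.DataFrame([results.to_row()])}
    elif hasattr(results, "tables"):  # PresetResult
        tables = dict(results.tables)
        extra.setdefault("preset", results.name)
        extra.setdefault("checks", [
            {"name": c.name, "passed": c.passed, "detail": c.detail}
            for c in results.checks])
    elif hasattr(results, "frame"):  # SweepResult
        tables = {"sweep": results.frame()}
    elif isinstance(results, dict):
        tables = results
    else:
        raise TypeError(f"cannot serialize results of type {type(results)!r}")

    for name, df in tables.items():
        path = out_dir / f"{name}.csv"
        _write_csv(df, path)
        written.append(path)
    written.append(write_metadata(out_dir, p=p, opts=opts, extra=extra))
    return written
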