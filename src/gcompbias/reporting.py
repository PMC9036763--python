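"""Tidy and wide CSV writers plus the per-run manifest."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from gcompbias.simulation_study import SimulationSummary

__all__ = ["RunManifest", "summaries_to_tidy", "summaries_to_wide",
           "write_summaries"]

_CONDITION_COLS = ["scenario", "n", "adjustment", "beta1"]


@dataclass(frozen=True)
class RunManifest:
    command: str
    config: dict
    seed: int
    version: str
    started: str
    finished: str
    outputs: list

    def write(self, out_dir: Path) -> Path:
        path = Path(out_dir) / "manifest.json"
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)
            fh.write("\n")
        return path


def summaries_to_wide(summaries: list) -> pd.DataFrame:
    """One row per condition, all bias/SE columns side by side."""
    cols = [f.name for f in dataclasses.fields(SimulationSummary)]
    return pd.DataFrame(
        [[getattr(s, c) for c in cols] for s in summaries], columns=cols
    )


def summaries_to_tidy(summaries: list) -> pd.DataFrame:
    """One row per condition x contrast: bias, empirical SE, mean, truth."""
    rows = []
    for s in summaries:
        for contrast in ("10", "01", "11"):
            rows.append({
                "scenario": s.scenario,
                "n": s.n,
                "adjustment": s.adjustment,
                "beta1": s.beta1,
                "contrast": contrast,
                "bias": getattr(s, f"bias_{contrast}"),
                "se": getattr(s, f"se_{contrast}"),
                "mean_estimate": getattr(s, f"mean_{contrast}"),
                "truth": getattr(s, f"truth_{contrast}"),
                "n_nonconverged": s.n_nonconverged,
                "n_reps_used": s.n_reps_used,
            })
    columns = _CONDITION_COLS + ["contrast", "bias", "se", "mean_estimate",
                                 "truth", "n_nonconverged", "n_reps_used"]
    return pd.DataFrame(rows, columns=columns)


def write_summaries(
    summaries: list,
    out_dir,
    command: str = "simulate",
    config: dict | None = None,
    seed: int = 0,
    started: str | None = None,
) -> RunManifest:
    """Write ``summaries_tidy.csv``, ``summaries_wide.csv`` and the manifest.

    Idempotent: re-running with the same inputs overwrites byte-identical
    CSV bodies (only the manifest timestamps differ).
    """
    from gcompbias import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tidy_path = out_dir / "summaries_tidy.csv"
    wide_path = out_dir / "summaries_wide.csv"
    summaries_to_tidy(summaries).to_csv(tidy_path, index=False)
    summaries_to_wide(summaries).to_csv(wide_path, index=False)
    now = datetime.now(timezone.utc).isoformat()
    manifest = RunManifest(
        command=command,
        config=config or {},
        seed=seed,
        version=__version__,
        started=started or now,
        finished=now,
        outputs=[str(tidy_path), str(wide_path)],
    )
    manifest.write(out_dir)
    return manifest
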