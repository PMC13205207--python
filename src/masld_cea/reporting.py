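"""Run manifests, CSV outputs, and optional figures.

Every CLI invocation writes a ``manifest.json`` recording the seed, the
config hash, the package version, the analyses run, and the output files,
so each output is traceable to exactly one manifest.  All randomness in a
run flows from one manifest seed through named substreams
(:func:`substream`), so each analysis is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .params import ParameterSet

__all__ = ["RunManifest", "substream", "write_csv", "million",
           "plot_ceac", "plot_ce_plane", "plot_tornado"]

_SUBSTREAMS = ("cascade", "psa", "microsim", "scenario", "twoway")


def substream(seed: int, name: str) -> int:
    """Derive a named child seed (< 2**31) from the manifest seed."""
    if name not in _SUBSTREAMS:
        raise ValueError(f"unknown substream {name!r}; one of {_SUBSTREAMS}")
    child = np.random.SeedSequence([seed, _SUBSTREAMS.index(name)])
    return int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass
class RunManifest:
    """Provenance record for one CLI run."""

    seed: int
    config_hash: str
    command: str
    version: str = __version__
    scenario_set: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    timestamp: str = field(
        default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat())
    notes: list[str] = field(default_factory=list)

    @classmethod
    def create(cls, seed: int, params: ParameterSet, command: str,
               synthetic_prevalence: bool = True) -> "RunManifest":
        m = cls(seed=seed, config_hash=params.config_hash(), command=command)
        if synthetic_prevalence:
            m.notes.append(
                "age-specific prevalence is a SYNTHETIC profile; absolute "
                "cost/QALY figures are conditional on it")
        return m

    def record(self, path: Path) -> Path:
        self.outputs.append(str(path))
        return path

    def write(self, out_dir: Path) -> Path:
        path = Path(out_dir) / "manifest.json"
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)
        return path


def write_csv(df: pd.DataFrame, out_dir: Path, name: str,
              manifest: RunManifest | None = None) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / name
    df.to_csv(path, index=False)
    if manifest is not None:
        manifest.record(path)
    return path


def million(usd: float, digits: int = 2) -> float:
    """Convert USD to the 'million $' reporting convention."""
    return round(usd / 1e6, digits)


# ---------------------------------------------------------------------------
# figures (optional; PNG only)

def _mpl():
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    return plt


def plot_ceac(curve, path: Path) -> Path:
    """Acceptability curves: P(optimal) per strategy over the WTP grid."""
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for sid in curve.optimal.columns:
        ax.plot(curve.wtp, curve.optimal[sid], label=sid)
    ax.set_xlabel("Willingness-to-pay ($/QALY)")
    ax.set_ylabel("Probability optimal")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_ce_plane(psa_results: pd.DataFrame, path: Path,
                  reference: str = "S4") -> Path:
    """Incremental cost-effectiveness plane of PSA iterations vs reference."""
    plt = _mpl()
    wide_c = psa_results.pivot(index="iteration", columns="strategy", values="cost")
    wide_q = psa_results.pivot(index="iteration", columns="strategy", values="qaly")
    fig, ax = plt.subplots(figsize=(6.5, 5))
    for sid in wide_c.columns:
        if sid == reference:
            continue
        ax.scatter(wide_q[sid] - wide_q[reference],
                   wide_c[sid] - wide_c[reference], s=6, alpha=0.4, label=sid)
    ax.axhline(0, color="grey", lw=0.6)
    ax.axvline(0, color="grey", lw=0.6)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost ($)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_tornado(table: pd.DataFrame, path: Path,
                 comparison: str = "icur_s2_vs_s4", top: int = 12) -> Path:
    """Horizontal bar chart of one-way ICUR swings, widest first."""
    plt = _mpl()
    params_order = (table.drop_duplicates("parameter").head(top)["parameter"])
    fig, ax = plt.subplots(figsize=(7, 0.45 * len(params_order) + 1.2))
    for i, p in enumerate(params_order):
        sub = table[table["parameter"] == p][comparison]
        ax.barh(i, sub.max() - sub.min(), left=sub.min(), height=0.6)
    ax.set_yticks(range(len(params_order)), params_order)
    ax.invert_yaxis()
    ax.set_xlabel(f"{comparison} ($/QALY)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
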