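"""Publication-style result tables, run manifests and figures."""
from __future__ import annotations

import datetime as _dt
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict

import pandas as pd

from . import __version__
from .config import ModelConfig
from .pipeline import BaseCaseResults

_EVENT_ROWS = (
    ("mi", "MI"),
    ("is", "IS"),
    ("hf", "HF"),
    ("fatal_cvd", "Fatal CVD"),
    ("revascularisation", "Revascularisation"),
    ("any_cvd", "Any CVD event"),
)

_COST_ROWS = (
    ("medication", "Medication"),
    ("non_fatal_acute", "Non-fatal acute CVD events"),
    ("fatal", "Fatal CVD events"),
    ("revascularisation", "Revascularisation"),
    ("post_event", "Post-event"),
    ("total", "Total cost"),
)


def results_table(results: BaseCaseResults) -> pd.DataFrame:
    """Base-case results shaped like a cost-effectiveness summary table:
    discounted LYs and ETPYs, undiscounted event counts, cost categories and
    the ICER, by arm with the increment."""
    t, c = results.treatment, results.control
    rows = [
        {"row": "Total LYs", "treatment": t.ly, "control": c.ly, "increment": t.ly - c.ly},
        {
            "row": "Total ETPYs",
            "treatment": t.etpy,
            "control": c.etpy,
            "increment": t.etpy - c.etpy,
        },
    ]
    for key, label in _EVENT_ROWS:
        rows.append(
            {
                "row": f"Events: {label}",
                "treatment": t.events[key],
                "control": c.events[key],
                "increment": t.events[key] - c.events[key],
            }
        )
    for key, label in _COST_ROWS:
        rows.append(
            {
                "row": f"Costs (BGN): {label}",
                "treatment": t.costs[key],
                "control": c.costs[key],
                "increment": t.costs[key] - c.costs[key],
            }
        )
    rows.append(
        {
            "row": "ICER (BGN/ETPY gained)",
            "treatment": float("nan"),
            "control": float("nan"),
            "increment": results.incremental.icer
            if results.incremental.icer is not None
            else float("nan"),
        }
    )
    return pd.DataFrame(rows)


def results_json(results: BaseCaseResults) -> Dict:
    inc = results.incremental
    return {
        "treatment": {
            "ly": results.treatment.ly,
            "etpy": results.treatment.etpy,
            "events": results.treatment.events,
            "costs": results.treatment.costs,
        },
        "control": {
            "ly": results.control.ly,
            "etpy": results.control.etpy,
            "events": results.control.events,
            "costs": results.control.costs,
        },
        "incremental": {
            "d_cost": inc.d_cost,
            "d_etpy": inc.d_etpy,
            "d_ly": inc.d_ly,
            "icer": inc.icer,
            "dominance": inc.dominance,
        },
        "event_rate_reduction": results.event_rate_reduction(),
    }


@dataclass
class RunManifest:
    """Provenance of one run: config hash, seed, version, outputs."""

    config_hash: str
    seed: int
    command: str
    outputs: Dict[str, str] = field(default_factory=dict)
    package_version: str = __version__
    timestamp: str = field(
        default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat()
    )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def write_base_case_outputs(
    results: BaseCaseResults, cfg: ModelConfig, out_dir, seed: int, command: str
) -> RunManifest:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table_path = out / "results.csv"
    json_path = out / "results.json"
    results_table(results).to_csv(table_path, index=False)
    with open(json_path, "w") as fh:
        json.dump(results_json(results), fh, indent=2)
    results.trace_treatment.to_csv(out / "trace_treatment.csv")
    results.trace_control.to_csv(out / "trace_control.csv")
    manifest = RunManifest(
        config_hash=cfg.content_hash(),
        seed=seed,
        command=command,
        outputs={
            "results_csv": str(table_path),
            "results_json": str(json_path),
            "trace_treatment": str(out / "trace_treatment.csv"),
            "trace_control": str(out / "trace_control.csv"),
        },
    )
    manifest.write(out / "manifest.json")
    return manifest


# -- figures ---------------------------------------------------------------


def plot_tornado(tornado: pd.DataFrame, path, top: int = 10) -> None:
    """Horizontal tornado diagram of the one-way sensitivity analysis."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = tornado.head(top).iloc[::-1]
    base = float(data["base_icer"].iloc[0]) if "base_icer" in data else 0.0
    fig, ax = plt.subplots(figsize=(7, 0.45 * len(data) + 1.5))
    for i, (_, rec) in enumerate(data.iterrows()):
        lo = min(rec["icer_low"], rec["icer_high"])
        hi = max(rec["icer_low"], rec["icer_high"])
        ax.barh(i, hi - lo, left=lo, color="#4878a8")
    ax.axvline(base, color="black", lw=1)
    ax.set_yticks(range(len(data)))
    ax.set_yticklabels(data["parameter"])
    ax.set_xlabel("ICER (BGN per ETPY gained)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ce_plane(psa, path) -> None:
    """Incremental cost vs incremental ETPY scatter of the PSA draws."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(psa.draws["d_etpy"], psa.draws["d_cost"], s=6, alpha=0.4)
    ax.scatter([psa.mean_d_etpy], [psa.mean_d_cost], color="red", s=30, zorder=3)
    ax.axhline(0, color="grey", lw=0.7)
    ax.axvline(0, color="grey", lw=0.7)
    ax.set_xlabel("Incremental ETPYs")
    ax.set_ylabel("Incremental cost (BGN)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
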