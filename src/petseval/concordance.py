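"""Per-case concordance between task-agnostic and task-based FoMs.

For an algorithm pair (A, B), every case gets signed B-minus-A deltas
in DSC, JSC, HD, and in the absolute normalized errors of MTV and TLG.
A case is *discordant* when the two FoM families disagree about which
algorithm served it better — e.g. B has the lower Dice but also the
lower MTV error. "Better" is oriented per FoM: higher DSC/JSC is
better, lower HD is better, lower aNE is better. Cases where either
delta is exactly zero form a separate "tied" stratum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: FoM name -> +1 if larger is better, -1 if smaller is better
_ORIENTATION = {
    "dsc": 1,
    "jsc": 1,
    "hd_mm": -1,
    "mtv_ane": -1,
    "tlg_ane": -1,
}

AGNOSTIC_FOMS = ("dsc", "jsc", "hd_mm")
TASK_FOMS = ("mtv_ane", "tlg_ane")


def compute_deltas(table: pd.DataFrame, alg_a: str, alg_b: str) -> pd.DataFrame:
    """Per-case B-minus-A deltas for every FoM.

    Sign convention: delta = value(second argument) - value(first
    argument). Only cases where both algorithms produced valid (finite)
    FoMs enter a given delta column; a coverage mismatch in case sets is
    an error listing the missing cases.
    """
    sub_a = table[table["algorithm"] == alg_a].set_index("case_id")
    sub_b = table[table["algorithm"] == alg_b].set_index("case_id")
    missing = sorted(set(sub_a.index) ^ set(sub_b.index))
    if missing:
        raise ValueError(f"algorithms cover different cases; mismatched: {missing}")
    cases = sorted(sub_a.index)
    out = pd.DataFrame({"case_id": cases})
    for fom in (*AGNOSTIC_FOMS, *TASK_FOMS):
        va = sub_a.loc[cases, fom].to_numpy(dtype=float)
        vb = sub_b.loc[cases, fom].to_numpy(dtype=float)
        out[f"delta_{fom}"] = vb - va
    out.attrs["pair"] = (alg_a, alg_b)
    return out


@dataclass
class DiscordanceSummary:
    agnostic_fom: str
    task_fom: str
    n_cases: int
    #: quadrant keys: (agnostic better/worse for B) x (task better/worse for B)
    quadrants: dict
    n_tied: int
    n_discordant: int

    def to_dict(self) -> dict:
        return {
            "agnostic_fom": self.agnostic_fom,
            "task_fom": self.task_fom,
            "n_cases": self.n_cases,
            "quadrants": self.quadrants,
            "n_tied": self.n_tied,
            "n_discordant": self.n_discordant,
            "discordant_fraction": (
                self.n_discordant / self.n_cases if self.n_cases else float("nan")
            ),
        }


def discordance_summary(
    deltas: pd.DataFrame, agnostic_fom: str, task_fom: str
) -> DiscordanceSummary:
    """Sign-quadrant counts for one agnostic/task FoM pairing.

    Deltas are first oriented so that a positive value means "B better";
    a discordant case has opposite orientations on the two axes. NaN
    deltas (e.g. an undefined HD from an empty mask) are counted as tied
    since no direction can be assigned.
    """
    if agnostic_fom not in AGNOSTIC_FOMS:
        raise ValueError(f"unknown task-agnostic FoM {agnostic_fom!r}")
    if task_fom not in TASK_FOMS:
        raise ValueError(f"unknown task-based FoM {task_fom!r}")
    da = deltas[f"delta_{agnostic_fom}"].to_numpy(dtype=float) * _ORIENTATION[agnostic_fom]
    dt = deltas[f"delta_{task_fom}"].to_numpy(dtype=float) * _ORIENTATION[task_fom]
    n = len(deltas)
    tied = (da == 0) | (dt == 0) | ~np.isfinite(da) | ~np.isfinite(dt)
    quadrants = {
        "b_better_both": int(((da > 0) & (dt > 0)).sum()),
        "b_better_agnostic_worse_task": int(((da > 0) & (dt < 0)).sum()),
        "b_worse_agnostic_better_task": int(((da < 0) & (dt > 0)).sum()),
        "b_worse_both": int(((da < 0) & (dt < 0)).sum()),
    }
    n_disc = (
        quadrants["b_better_agnostic_worse_task"]
        + quadrants["b_worse_agnostic_better_task"]
    )
    return DiscordanceSummary(
        agnostic_fom=agnostic_fom,
        task_fom=task_fom,
        n_cases=n,
        quadrants=quadrants,
        n_tied=int(tied.sum()),
        n_discordant=n_disc,
    )


def scatter_table(deltas: pd.DataFrame, agnostic_fom: str, task_fom: str) -> pd.DataFrame:
    """Two-column export of one delta-vs-delta scatter."""
    return deltas[["case_id", f"delta_{agnostic_fom}", f"delta_{task_fom}"]].copy()


def plot_scatter(deltas: pd.DataFrame, agnostic_fom: str, task_fom: str, path) -> None:
    """Delta-vs-delta scatter with zero lines, saved to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = deltas[f"delta_{agnostic_fom}"]
    y = deltas[f"delta_{task_fom}"]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(x, y, s=14, alpha=0.7, edgecolor="none")
    ax.axhline(0.0, color="gray", lw=0.8, ls="--")
    ax.axvline(0.0, color="gray", lw=0.8, ls="--")
    pair = deltas.attrs.get("pair", ("A", "B"))
    ax.set_xlabel(f"Δ {agnostic_fom.upper()} ({pair[1]} - {pair[0]})")
    ax.set_ylabel(f"Δ {task_fom} ({pair[1]} - {pair[0]})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
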