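"""SILAC depletion screen.

Three independent SILAC experiments compare a kinase double-knockout (DKO)
against wild type (WT), each in forward and reverse labelling orientation;
reverse ratios are reciprocal-corrected at ingestion so every value is
log2(DKO/WT).  A site is called depleted in an experiment when both
orientations fall below the depletion threshold (default -1.5, strict
inequality), or under the alternative rule when the orientation mean does.
WT/WT control mixes expose label-dependent artifacts: any control ratio
outside the +/- control band excludes the site from the combined call.

Proteins whose detected sites are almost uniformly depleted are flagged as
potential protein-level changes (abundance, not phosphorylation) -- a
caution annotation, never a removal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

from .io import EXPERIMENTS, silac_col

Call = Literal["depleted", "not_depleted", "incomplete"]

COMBINE_RULES = ("both_orientations", "mean_of_orientations")


@dataclass
class SilacThresholds:
    """Thresholds for the depletion screen.

    depletion_log2:
        Per-orientation (or orientation-mean) log2(DKO/WT) cutoff; a site
        must fall strictly below it.  Negative by definition.
    control_band:
        Half-width of the accepted WT/WT control band; |log2(WT/WT)|
        strictly above it flags label bias.
    combine_rule:
        'both_orientations' (each orientation below the cutoff) or
        'mean_of_orientations' (orientation mean below the cutoff).
    min_experiments:
        Depletion calls required across the three experiments.
    """

    depletion_log2: float = -1.5
    control_band: float = 0.5
    combine_rule: str = "both_orientations"
    min_experiments: int = 1

    def __post_init__(self):
        if not self.depletion_log2 < 0:
            raise ValueError("depletion_log2 must be negative")
        if not self.control_band > 0:
            raise ValueError("control_band must be positive")
        if self.combine_rule not in COMBINE_RULES:
            raise ValueError(f"combine_rule must be one of {COMBINE_RULES}")
        if self.min_experiments not in (1, 2, 3):
            raise ValueError("min_experiments must be 1, 2 or 3")


@dataclass
class DepletionCall:
    """Per-site outcome of the combined screen."""

    site_id: str
    per_experiment: Mapping[int, Call] = field(default_factory=dict)
    label_biased: bool = False
    combined_depleted: bool = False


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def call_depletion_per_experiment(
    fwd: float | None, rev: float | None, thresholds: SilacThresholds
) -> Call:
    """Depletion call from one experiment's forward/reverse log2(DKO/WT) pair."""
    if _is_missing(fwd) or _is_missing(rev):
        return "incomplete"
    t = thresholds.depletion_log2
    if thresholds.combine_rule == "both_orientations":
        depleted = fwd < t and rev < t
    else:
        depleted = (fwd + rev) / 2.0 < t
    return "depleted" if depleted else "not_depleted"


def flag_label_bias(control_log2: Iterable[float], thresholds: SilacThresholds) -> bool:
    """True iff any WT/WT control log2 ratio lies strictly outside the band."""
    return any(
        not _is_missing(c) and abs(c) > thresholds.control_band for c in control_log2
    )


def combine_experiments(
    site_id: str,
    per_experiment: Mapping[int, Call],
    label_biased: bool,
    thresholds: SilacThresholds,
) -> DepletionCall:
    """Combined call: enough experiments depleted, and no label bias."""
    n_depleted = sum(1 for c in per_experiment.values() if c == "depleted")
    return DepletionCall(
        site_id=site_id,
        per_experiment=dict(per_experiment),
        label_biased=label_biased,
        combined_depleted=(n_depleted >= thresholds.min_experiments) and not label_biased,
    )


def flag_protein_level_change(
    combined_depleted: Iterable[bool], min_sites: int = 3, min_fraction: float = 0.8
) -> bool:
    """Protein-level-change heuristic over one protein's site calls.

    True when the protein carries at least ``min_sites`` detected sites of
    which at least ``min_fraction`` are depleted -- a coordinate decrease
    more consistent with protein abundance change than with loss of a
    specific phosphorylation.
    """
    calls = list(combined_depleted)
    if len(calls) < min_sites:
        return False
    return sum(calls) / len(calls) >= min_fraction


def screen(
    sites: pd.DataFrame,
    thresholds: SilacThresholds | None = None,
    protein_level_min_sites: int = 3,
    protein_level_min_fraction: float = 0.8,
) -> pd.DataFrame:
    """Run the depletion screen over a wide site table.

    Expects ``silac_exp{e}_{fwd,rev,ctrl}`` columns; returns one row per
    site with per-experiment calls, the label-bias flag, the combined
    depletion call and the protein-level caution flag.
    """
    thresholds = thresholds or SilacThresholds()
    out = sites[["site_id", "gene"]].copy()

    t = thresholds.depletion_log2
    depleted_any = []
    for e in EXPERIMENTS:
        fwd = sites[silac_col(e, "fwd")]
        rev = sites[silac_col(e, "rev")]
        incomplete = fwd.isna() | rev.isna()
        if thresholds.combine_rule == "both_orientations":
            depl = (fwd < t) & (rev < t)
        else:
            depl = (fwd + rev) / 2.0 < t
        depl = depl & ~incomplete
        out[f"exp{e}_call"] = np.select(
            [incomplete, depl], ["incomplete", "depleted"], default="not_depleted"
        )
        depleted_any.append(depl)

    n_depleted = sum(d.astype(int) for d in depleted_any)
    ctrl = sites[[silac_col(e, "ctrl") for e in EXPERIMENTS]]
    biased = (ctrl.abs() > thresholds.control_band).any(axis=1)

    out["n_experiments_depleted"] = n_depleted
    out["label_biased"] = biased.to_numpy()
    out["combined_depleted"] = (
        (n_depleted >= thresholds.min_experiments) & ~biased
    ).to_numpy()

    frac = out.groupby("gene")["combined_depleted"].transform("mean")
    nsite = out.groupby("gene")["combined_depleted"].transform("size")
    out["protein_level_flag"] = (
        (nsite >= protein_level_min_sites) & (frac >= protein_level_min_fraction)
    ).to_numpy()
    return out


def scatter_table(sites: pd.DataFrame, experiment: int) -> pd.DataFrame:
    """Forward/reverse log2 pairs with scatterplot quadrant labels.

    The lower-left quadrant is where depleted sites live (both ratios
    negative); labels use >= 0 as right/upper.
    """
    fwd = sites[silac_col(experiment, "fwd")]
    rev = sites[silac_col(experiment, "rev")]
    quadrant = np.select(
        [
            (fwd < 0) & (rev < 0),
            (fwd >= 0) & (rev < 0),
            (fwd < 0) & (rev >= 0),
        ],
        ["lower_left", "lower_right", "upper_left"],
        default="upper_right",
    )
    quadrant = np.where(fwd.isna() | rev.isna(), "incomplete", quadrant)
    return pd.DataFrame(
        {
            "site_id": sites["site_id"],
            "fwd_log2": fwd,
            "rev_log2": rev,
            "quadrant": quadrant,
        }
    ).reset_index(drop=True)
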