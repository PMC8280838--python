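"""TMT time-course screen: normalization, triage variables, clustering, tiers.

A 10-plex TMT run quantifies every phosphopeptide across WT and DKO
genotypes at 0/10/30/60 min of starvation plus a refed (RF) condition.
Profiles are triaged with three log10-scale contrasts plus a similarity
variable:

    V1 = WT60 - WT0     starvation-induced gain in WT
    V2 = WT60 - DKO60   kinase dependence at 60 min
    V3 = WT60 - WTRF    reversal on refeeding
    V4 = Pearson r against a reference substrate profile

Sites passing all of V1-V3 form the primary tier (takes precedence);
sites failing that but with V4 strictly above ``r_min`` (default 0.7) form
the similarity tier; everything else is tier ``none``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .io import TMT_CONDITIONS, TMT_COLUMNS, tmt_col

NORMALIZATION_MODES = ("log10_raw", "anchored_to_DKO0", "relative_log2")
TIERS = ("primary", "similarity_only", "none")

#: Label for zero-variance profiles set aside by correlation clustering.
FLAT_CLUSTER = 0


@dataclass
class TmtThresholds:
    """Triage thresholds, in log10(TMT enrichment) units for theta1..3."""

    theta1: float = 0.1
    theta2: float = 0.1
    theta3: float = 0.1
    r_min: float = 0.7

    def __post_init__(self):
        if not -1.0 <= self.r_min <= 1.0:
            raise ValueError("r_min must be within [-1, 1]")


def complete_profiles_only(profiles: pd.DataFrame) -> pd.DataFrame:
    """Retain profiles detected (positive) in all 10 conditions."""
    cols = list(TMT_COLUMNS)
    mask = profiles[cols].notna().all(axis=1) & (profiles[cols] > 0).all(axis=1)
    return profiles.loc[mask].reset_index(drop=True)


def normalize(profiles: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Normalize complete, positive profiles.

    log10_raw:        value = log10(intensity)
    anchored_to_DKO0: value = log10(intensity) - log10(intensity at DKO 0 min)
    relative_log2:    value = log2(intensity / mean intensity over the 10
                      conditions) -- the heat-map normalization.
    """
    if mode not in NORMALIZATION_MODES:
        raise ValueError(f"mode must be one of {NORMALIZATION_MODES}")
    cols = list(TMT_COLUMNS)
    vals = profiles[cols].to_numpy(dtype=float)
    bad = ~(vals > 0)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        site = profiles.iloc[r]["site_id"] if "site_id" in profiles.columns else r
        raise ValueError(
            f"non-positive intensity at condition {TMT_CONDITIONS[c]} (site {site})"
        )
    if mode == "log10_raw":
        norm = np.log10(vals)
    elif mode == "anchored_to_DKO0":
        anchor = np.log10(vals[:, [cols.index(tmt_col("DKO_0"))]])
        norm = np.log10(vals) - anchor
    else:
        norm = np.log2(vals / vals.mean(axis=1, keepdims=True))
    out = profiles.copy()
    out[cols] = norm
    return out


def profile_matrix(normalized: pd.DataFrame) -> np.ndarray:
    """(n_sites, 10) array of normalized values in the fixed condition order."""
    return normalized[list(TMT_COLUMNS)].to_numpy(dtype=float)


def triage_variables(
    normalized: pd.DataFrame, reference: pd.Series
) -> pd.DataFrame:
    """Compute V1-V4 per profile against a reference profile.

    ``reference`` is indexed by the 10 condition names, in the same
    normalization mode as ``normalized``.  V1-V3 are identical between
    ``log10_raw`` and ``anchored_to_DKO0`` modes (the anchor cancels).
    """
    ref = reference.reindex(list(TMT_CONDITIONS)).to_numpy(dtype=float)
    if np.isnan(ref).any():
        raise ValueError("reference profile incomplete")
    if np.std(ref) == 0:
        raise ValueError("reference profile is constant; correlation undefined")

    X = profile_matrix(normalized)
    v = lambda cond: X[:, list(TMT_CONDITIONS).index(cond)]
    v1 = v("WT_60") - v("WT_0")
    v2 = v("WT_60") - v("DKO_60")
    v3 = v("WT_60") - v("WT_RF")

    Xc = X - X.mean(axis=1, keepdims=True)
    rc = ref - ref.mean()
    denom = np.linalg.norm(Xc, axis=1) * np.linalg.norm(rc)
    with np.errstate(invalid="ignore", divide="ignore"):
        v4 = np.where(denom > 0, Xc @ rc / denom, np.nan)

    return pd.DataFrame(
        {"site_id": normalized["site_id"], "V1": v1, "V2": v2, "V3": v3, "V4": v4}
    ).reset_index(drop=True)


def assign_tier(
    variables: pd.DataFrame, thresholds: TmtThresholds | None = None
) -> pd.DataFrame:
    """Tier assignment with primary-tier precedence.

    primary:         V1 >= theta1 and V2 >= theta2 and V3 >= theta3
    similarity_only: not primary, V4 strictly > r_min
    none:            otherwise (constant profiles have undefined V4 and
                     can only be tier none).
    """
    th = thresholds or TmtThresholds()
    primary = (
        (variables["V1"] >= th.theta1)
        & (variables["V2"] >= th.theta2)
        & (variables["V3"] >= th.theta3)
    )
    similar = ~primary & (variables["V4"] > th.r_min)
    out = variables.copy()
    out["tier"] = np.select([primary, similar], ["primary", "similarity_only"], "none")
    return out


def select_most_variable(normalized: pd.DataFrame, n: int) -> pd.DataFrame:
    """Top-``n`` profiles by variance across the 10 conditions.

    Deterministic: ties broken by site_id.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    var = profile_matrix(normalized).var(axis=1)
    order = (
        pd.DataFrame({"site_id": normalized["site_id"], "_var": var})
        .sort_values(["_var", "site_id"], ascending=[False, True], kind="mergesort")
        .index[:n]
    )
    return normalized.loc[sorted(order)].reset_index(drop=True)


def correlation_cluster(
    normalized: pd.DataFrame, k: int, flat_tol: float = 1e-9
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Hierarchical correlation clustering of time-course profiles.

    Distance 1 - Pearson(profile_i, profile_j), average linkage, tree cut
    at ``k`` clusters.  Zero-variance ("flat") profiles cannot enter a
    correlation distance and are set aside in a dedicated cluster labelled
    ``FLAT_CLUSTER`` (0).  Deterministic and invariant to input row order:
    profiles are canonicalized by site_id before clustering, and final
    labels 1..k are ordered by (cluster size desc, smallest site_id).

    Returns (labels, cluster_means): ``labels`` maps site_id -> cluster;
    ``cluster_means`` holds the average profile per cluster across the 10
    conditions (the per-cluster mean WT and DKO time courses).
    """
    work = normalized.sort_values("site_id", kind="mergesort").reset_index(drop=True)
    X = profile_matrix(work)
    sd = X.std(axis=1)
    flat = sd <= flat_tol

    labels = np.zeros(len(work), dtype=int)
    active = np.flatnonzero(~flat)
    if active.size:
        if active.size < k:
            raise ValueError(f"need at least k={k} non-flat profiles, have {active.size}")
        Xa = X[active]
        Xc = (Xa - Xa.mean(axis=1, keepdims=True)) / (
            Xa.std(axis=1, keepdims=True) * np.sqrt(Xa.shape[1])
        )
        corr = np.clip(Xc @ Xc.T, -1.0, 1.0)
        dist = 1.0 - corr
        np.fill_diagonal(dist, 0.0)
        condensed = squareform(dist, checks=False)
        link = sch.linkage(condensed, method="average")
        raw = sch.fcluster(link, t=k, criterion="maxclust")

        # deterministic relabelling: big clusters first, ties by first site_id
        ids = work["site_id"].to_numpy()[active]
        order = sorted(
            np.unique(raw),
            key=lambda c: (-(raw == c).sum(), ids[raw == c].min()),
        )
        remap = {c: i + 1 for i, c in enumerate(order)}
        labels[active] = [remap[c] for c in raw]

    label_df = pd.DataFrame({"site_id": work["site_id"], "cluster": labels})
    means = (
        pd.concat([label_df, work[list(TMT_COLUMNS)]], axis=1)
        .groupby("cluster")[list(TMT_COLUMNS)]
        .mean()
    )
    return label_df, means
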