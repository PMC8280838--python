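"""Synthetic two-screen generator with planted ground truth.

Emulates the study design end to end so every pipeline stage has a
recovery test without any deposited data: three SILAC experiments with
forward/reverse labelling and WT/WT control mixes, and a TMT 10-plex over
WT/DKO at 0/10/30/60 min starvation plus refeed.  Five planted site
classes:

true_substrate
    Motif-conforming window; strong log2(DKO/WT) depletion shared across
    orientations and experiments; the substrate time-course dynamic (WT
    rise on starvation, reversal on refeed, DKO flat at a lower baseline).
label_bias
    Looks depleted in DKO/WT but carries WT/WT control artifacts outside
    the control band -- the class the control exclusion must catch.
protein_level
    All sites of one protein share a common depletion offset with
    divergent, non-motif windows and low-conservation human orthologs:
    protein abundance change masquerading as dephosphorylation.
proline_background
    +1-proline windows with a ULK-independent starvation response of
    opposite sign in both genotypes (the proline-directed kinase
    background visible in depleted-site logos).
null
    Centred noise everywhere.

A noiseless reference control site ``Prkab2_S38`` carrying the exact
substrate template is always planted (synthetic window -- a stand-in for
the real reference substrate, not its sequence), so similarity triage has
its default reference in-table.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import motif as motif_mod
from .io import (
    AMINO_ACIDS,
    CENTER_INDEX,
    EXPERIMENTS,
    TMT_CONDITIONS,
    make_site_id,
    silac_col,
    tmt_col,
    write_edge_list,
    write_results,
)

TRUTH_CLASSES = (
    "true_substrate",
    "label_bias",
    "protein_level",
    "proline_background",
    "null",
)

REFERENCE_SITE_ID = "Prkab2_S38"


@dataclass
class TmtDynamics:
    """Planted substrate time-course shape, log10(TMT enrichment) units.

    WT follows baseline + rise over 0/10/30/60 min, dropping to
    ``refeed_level`` above baseline on refeeding; DKO sits flat at
    baseline - ``dko_deficit``.
    """

    baseline_log10: float = 5.0
    baseline_sd: float = 0.5
    starvation_rise: tuple = (0.0, 0.1, 0.25, 0.4)
    refeed_level: float = 0.1
    dko_deficit: float = 0.3


@dataclass
class GeneratorConfig:
    """Study-condition parameters for one synthetic screen.

    Defaults follow the screen design: ~10,000 sites over 2,000 proteins,
    5 true substrates per 1,000 sites, depletion well past the -1.5
    threshold, and measurement noise typical of log-ratio proteomics.
    """

    n_proteins: int = 2000
    mean_sites_per_protein: float = 5.0
    n_true_substrates: int | None = None  # None -> substrate_rate applies
    substrate_rate: float = 0.005  # per site
    substrate_effect_mean: float = -2.5
    substrate_effect_sd: float = 0.3
    substrate_effect_max: float = -1.8  # truncation: planted = highly depleted
    fraction_label_bias_artifacts: float = 0.01
    fraction_protein_level_changers: float = 0.005  # of proteins
    fraction_proline_directed_background: float = 0.15
    fraction_low_conservation_null: float = 0.02
    noise_sd_silac: float = 0.4  # log2, per orientation
    noise_sd_control: float = 0.15  # log2, WT/WT mixes
    noise_sd_tmt: float = 0.05  # log10, per condition
    fraction_missing_silac: float = 0.1  # per site x experiment
    fraction_incomplete_tmt: float = 0.05  # per site: one condition dropped
    ppi_fraction_within_2: float = 0.8  # true-substrate genes near the anchors
    tmt_dynamics: TmtDynamics = field(default_factory=TmtDynamics)
    motif_notation: str = motif_mod.ULK1_MOTIF
    seed: int = 0

    def __post_init__(self):
        fracs = (
            self.fraction_label_bias_artifacts
            + self.fraction_proline_directed_background
            + self.substrate_rate
        )
        if fracs > 1:
            raise ValueError("site-class fractions exceed 1")
        for name in ("noise_sd_silac", "noise_sd_control", "noise_sd_tmt"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not self.substrate_effect_max < 0:
            raise ValueError("substrate_effect_max must be negative")

    def noiseless(self) -> "GeneratorConfig":
        """Copy with all measurement noise and missingness switched off."""
        return dataclasses.replace(
            self,
            noise_sd_silac=0.0,
            noise_sd_control=0.0,
            noise_sd_tmt=0.0,
            fraction_missing_silac=0.0,
            fraction_incomplete_tmt=0.0,
        )


@dataclass
class SyntheticScreen:
    """Generated tables plus planted truth."""

    sites: pd.DataFrame
    orthologs: pd.DataFrame
    ppi_edges: list
    truth: pd.DataFrame
    config: GeneratorConfig

    def truth_sites(self, truth_class: str) -> set:
        return set(self.truth.loc[self.truth["truth_class"] == truth_class, "site_id"])

    def write(self, out_dir: str | Path) -> None:
        import networkx as nx

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_results(self.sites, out / "sites.tsv")
        self.orthologs.to_csv(out / "orthologs.tsv", sep="\t", index=False, lineterminator="\n")
        graph = nx.Graph()
        graph.add_edges_from(self.ppi_edges)
        write_edge_list(graph, out / "ppi_edges.tsv")
        self.truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False, lineterminator="\n")


def _truncated_normal(rng, mean, sd, upper, size):
    """Normal draws conditioned on being <= upper (rejection sampling)."""
    out = rng.normal(mean, sd, size)
    bad = out > upper
    while bad.any():
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = out > upper
    return out


def _motif_conforming_window(rng, motif: motif_mod.Motif, residue: str) -> str:
    letters = list(rng.choice(list(AMINO_ACIDS), size=15))
    for off, pos in motif.positions.items():
        choices = sorted((pos.allowed or set(AMINO_ACIDS)) - pos.forbidden)
        letters[CENTER_INDEX + off] = str(rng.choice(choices))
    letters[CENTER_INDEX] = residue
    return "".join(letters)


def _random_windows(rng, n: int) -> np.ndarray:
    aa = np.array(list(AMINO_ACIDS))
    return aa[rng.integers(0, len(aa), size=(n, 15))]


def reference_profile(config: GeneratorConfig | None = None) -> pd.Series:
    """The planted reference substrate profile as raw TMT intensities.

    Monotone WT increase over starvation, refeed below the 60-min value,
    DKO flat at a lower baseline; returned on the intensity scale, indexed
    by the 10 condition names.
    """
    dyn = (config or GeneratorConfig()).tmt_dynamics
    base = dyn.baseline_log10
    log10 = {}
    for t, rise in zip(("0", "10", "30", "60"), dyn.starvation_rise):
        log10[f"WT_{t}"] = base + rise
    log10["WT_RF"] = base + dyn.refeed_level
    for t in ("0", "10", "30", "60", "RF"):
        log10[f"DKO_{t}"] = base - dyn.dko_deficit
    return pd.Series({c: 10.0 ** log10[c] for c in TMT_CONDITIONS})


def _site_log10_template(dyn: TmtDynamics, truth_class: str, base: float) -> np.ndarray:
    """Noiseless log10 profile for one site of a given class."""
    rises = dict(zip(("0", "10", "30", "60"), dyn.starvation_rise))
    vals = {}
    if truth_class == "true_substrate":
        for t, r in rises.items():
            vals[f"WT_{t}"] = base + r
        vals["WT_RF"] = base + dyn.refeed_level
        for t in ("0", "10", "30", "60", "RF"):
            vals[f"DKO_{t}"] = base - dyn.dko_deficit
    elif truth_class == "protein_level":
        for t in ("0", "10", "30", "60", "RF"):
            vals[f"WT_{t}"] = base
            vals[f"DKO_{t}"] = base - dyn.dko_deficit
    elif truth_class == "proline_background":
        # ULK-independent starvation response, opposite in sign and shared
        # by both genotypes (mTORC1-substrate-like: dephosphorylated on
        # starvation, recovering on refeed)
        for t, r in rises.items():
            vals[f"WT_{t}"] = base - r
            vals[f"DKO_{t}"] = base - r
        vals["WT_RF"] = base - dyn.refeed_level
        vals["DKO_RF"] = base - dyn.refeed_level
    else:  # null, label_bias: flat in both genotypes
        for t in ("0", "10", "30", "60", "RF"):
            vals[f"WT_{t}"] = base
            vals[f"DKO_{t}"] = base
    return np.array([vals[c] for c in TMT_CONDITIONS])


def generate_screen(config: GeneratorConfig | None = None) -> SyntheticScreen:
    """Generate one synthetic two-screen data set with planted ground truth."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    motif = motif_mod.parse_motif(config.motif_notation)

    # --- protein and site scaffold ------------------------------------
    genes = [f"G{i:04d}" for i in range(config.n_proteins)]
    sites_per = 1 + rng.poisson(max(config.mean_sites_per_protein - 1.0, 0.0), config.n_proteins)
    gene_of_site = np.repeat(np.arange(config.n_proteins), sites_per)
    n_sites = len(gene_of_site)

    positions = np.empty(n_sites, dtype=int)
    for g in range(config.n_proteins):
        idx = np.flatnonzero(gene_of_site == g)
        positions[idx] = np.sort(
            rng.choice(np.arange(1, 2001), size=len(idx), replace=False)
        )
    residues = np.array(list(rng.choice(["S", "T", "Y"], p=[0.65, 0.25, 0.10], size=n_sites)))

    # --- class assignment ---------------------------------------------
    truth = np.array(["null"] * n_sites, dtype=object)

    n_pl_proteins = int(round(config.fraction_protein_level_changers * config.n_proteins))
    pl_proteins = rng.choice(config.n_proteins, size=n_pl_proteins, replace=False)
    truth[np.isin(gene_of_site, pl_proteins)] = "protein_level"

    free = np.flatnonzero(truth == "null")
    n_sub = (
        config.n_true_substrates
        if config.n_true_substrates is not None
        else int(round(config.substrate_rate * n_sites))
    )
    n_bias = int(round(config.fraction_label_bias_artifacts * n_sites))
    n_pro = int(round(config.fraction_proline_directed_background * n_sites))
    if n_sub + n_bias + n_pro > len(free):
        raise ValueError("infeasible config: class counts exceed available sites")
    picked = rng.choice(free, size=n_sub + n_bias + n_pro, replace=False)
    truth[picked[:n_sub]] = "true_substrate"
    truth[picked[n_sub : n_sub + n_bias]] = "label_bias"
    truth[picked[n_sub + n_bias :]] = "proline_background"

    # phosphoacceptor constraints: substrates and proline background are S/T
    st_mask = np.isin(truth, ("true_substrate", "proline_background"))
    residues[st_mask & (residues == "Y")] = "S"

    # --- windows --------------------------------------------------------
    win = _random_windows(rng, n_sites)
    win[:, CENTER_INDEX] = residues
    windows = np.array(["".join(row) for row in win], dtype=object)
    for i in np.flatnonzero(truth == "true_substrate"):
        windows[i] = _motif_conforming_window(rng, motif, residues[i])
    for i in np.flatnonzero(truth == "proline_background"):
        w = list(windows[i])
        w[CENTER_INDEX + 1] = "P"
        windows[i] = "".join(w)
    for i in np.flatnonzero(truth == "protein_level"):
        if motif_mod.match(motif, windows[i]):
            w = list(windows[i])
            w[CENTER_INDEX - 3] = "A"  # A is outside the -3 allowed set
            windows[i] = "".join(w)

    sites = pd.DataFrame(
        {
            "gene": [genes[g] for g in gene_of_site],
            "protein": [f"P{g:04d}" for g in gene_of_site],
            "residue": residues,
            "position": positions,
            "window": windows,
            "localization_prob": np.round(rng.uniform(0.76, 1.0, n_sites), 4),
        }
    )
    sites.insert(
        0,
        "site_id",
        [make_site_id(g, r, p) for g, r, p in zip(sites["gene"], residues, positions)],
    )

    # --- SILAC ratios ---------------------------------------------------
    effect = np.zeros(n_sites)
    sub_idx = np.flatnonzero(truth == "true_substrate")
    effect[sub_idx] = _truncated_normal(
        rng,
        config.substrate_effect_mean,
        config.substrate_effect_sd,
        config.substrate_effect_max,
        len(sub_idx),
    )
    bias_idx = np.flatnonzero(truth == "label_bias")
    effect[bias_idx] = _truncated_normal(
        rng,
        config.substrate_effect_mean,
        config.substrate_effect_sd,
        config.substrate_effect_max,
        len(bias_idx),
    )
    for g in pl_proteins:
        idx = np.flatnonzero(gene_of_site == g)
        effect[idx] = _truncated_normal(
            rng, -2.0, 0.3, config.substrate_effect_max, 1
        )[0]

    for e in EXPERIMENTS:
        for kind in ("fwd", "rev"):
            sites[silac_col(e, kind)] = effect + rng.normal(
                0.0, config.noise_sd_silac, n_sites
            )
        ctrl = rng.normal(0.0, config.noise_sd_control, n_sites)
        # label-bias artifacts: control ratios pushed outside the band,
        # alternating sign across experiments (label-dependent enrichment)
        sign = 1.0 if e % 2 else -1.0
        ctrl[bias_idx] = sign * (0.6 + np.abs(rng.normal(0.0, 0.2, len(bias_idx))))
        sites[silac_col(e, "ctrl")] = ctrl
        if config.fraction_missing_silac > 0:
            missing = rng.random(n_sites) < config.fraction_missing_silac
            for kind in ("fwd", "rev"):
                sites.loc[missing, silac_col(e, kind)] = np.nan

    # --- TMT profiles ----------------------------------------------------
    dyn = config.tmt_dynamics
    bases = rng.normal(dyn.baseline_log10, dyn.baseline_sd, n_sites)
    log10 = np.vstack(
        [_site_log10_template(dyn, truth[i], bases[i]) for i in range(n_sites)]
    )
    log10 += rng.normal(0.0, config.noise_sd_tmt, log10.shape)
    intensities = 10.0 ** log10
    if config.fraction_incomplete_tmt > 0:
        incomplete = rng.random(n_sites) < config.fraction_incomplete_tmt
        drop_cond = rng.integers(0, len(TMT_CONDITIONS), n_sites)
        for i in np.flatnonzero(incomplete):
            intensities[i, drop_cond[i]] = np.nan
    for j, cond in enumerate(TMT_CONDITIONS):
        sites[tmt_col(cond)] = intensities[:, j]

    # --- reference control site (noiseless template) ---------------------
    ref_window = _motif_conforming_window(rng, motif, "S")
    ref_row = {
        "site_id": REFERENCE_SITE_ID,
        "gene": "Prkab2",
        "protein": "PRKAB2",
        "residue": "S",
        "position": 38,
        "window": ref_window,
        "localization_prob": 1.0,
        **{
            silac_col(e, k): (config.substrate_effect_mean if k != "ctrl" else 0.0)
            for e in EXPERIMENTS
            for k in ("fwd", "rev", "ctrl")
        },
        **{tmt_col(c): v for c, v in reference_profile(config).items()},
    }
    sites = pd.concat([sites, pd.DataFrame([ref_row])], ignore_index=True)
    truth = np.append(truth, "true_substrate")
    windows = np.append(windows, ref_window)

    # --- ortholog window pairs -------------------------------------------
    human = windows.copy()
    divergent = set(np.flatnonzero(np.isin(truth, ("protein_level",))))
    null_idx = np.flatnonzero(truth == "null")
    n_div_null = int(round(config.fraction_low_conservation_null * len(null_idx)))
    divergent |= set(rng.choice(null_idx, size=n_div_null, replace=False))
    aa = np.array(list(AMINO_ACIDS))
    for i in sorted(divergent):
        w = list(human[i])
        mutate = rng.choice(
            [p for p in range(15) if p != CENTER_INDEX], size=9, replace=False
        )
        for p in mutate:
            w[p] = str(aa[rng.integers(0, len(aa))])
        human[i] = "".join(w)
    orthologs = pd.DataFrame(
        {
            "site_id": sites["site_id"],
            "window_mouse": windows,
            "window_human": human,
        }
    )

    # --- PPI edge list ----------------------------------------------------
    edges = [("ULK1", "ULK2"), ("ULK1", "ATG13"), ("ULK1", "RB1CC1"), ("ATG13", "ATG101")]
    sub_genes = sorted({sites["gene"].iloc[i] for i in sub_idx})
    for gene in sub_genes:
        u = rng.random()
        if u < config.ppi_fraction_within_2:
            if rng.random() < 0.5:
                edges.append((str(gene).upper(), "ULK1" if rng.random() < 0.5 else "ULK2"))
            else:
                edges.append((str(gene).upper(), "ATG13"))  # distance 2 via ATG13
        else:
            edges.append((str(gene).upper(), "FARAWAY1"))
    edges.append(("FARAWAY1", "FARAWAY2"))
    bg_genes = rng.choice(genes, size=min(100, len(genes)), replace=False)
    for a, b in zip(bg_genes[::2], bg_genes[1::2]):
        if a != b:
            edges.append((str(a).upper(), str(b).upper()))

    truth_df = pd.DataFrame({"site_id": sites["site_id"], "truth_class": truth})
    return SyntheticScreen(
        sites=sites, orthologs=orthologs, ppi_edges=edges, truth=truth_df, config=config
    )
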