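"""End-to-end screen: read, filter, call, triage, cross-reference, emit.

``run_all`` wires the stages in the same order the CLI subcommands expose
individually, writing every intermediate plus a provenance record (config
hash, package version, input hashes) so identical inputs and config give
byte-identical output directories.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import io, motif as motif_mod, shortlist as shortlist_mod, silac, tmt
from .config import PipelineConfig, config_hash, config_to_dict, save_config


class PipelineError(RuntimeError):
    pass


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def silac_stage(sites: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    return silac.screen(
        sites,
        config.silac,
        protein_level_min_sites=config.protein_level.min_sites,
        protein_level_min_fraction=config.protein_level.min_fraction,
    )


def tmt_stage(sites: pd.DataFrame, config: PipelineConfig, reference: pd.Series | None = None):
    """Complete-profile filter, normalization, triage and clustering.

    Returns (tiers, cluster labels, cluster means).  The reference profile
    is taken from ``config.reference_site`` within the table unless one is
    supplied; V1-V3 and V4 use the normalized values.
    """
    complete = tmt.complete_profiles_only(sites)
    if complete.empty:
        raise PipelineError("no complete TMT profiles in input")
    normalized = tmt.normalize(complete, config.tmt_normalization)

    if reference is None:
        ref_rows = normalized.loc[normalized["site_id"] == config.reference_site]
        if ref_rows.empty:
            raise PipelineError(
                f"reference site {config.reference_site!r} absent from the TMT table"
            )
        reference = ref_rows.iloc[0][list(io.TMT_COLUMNS)]
        reference.index = list(io.TMT_CONDITIONS)

    variables = tmt.triage_variables(normalized, reference)
    tiers = tmt.assign_tier(variables, config.tmt)

    to_cluster = normalized
    if config.clustering.n_most_variable is not None:
        to_cluster = tmt.select_most_variable(normalized, config.clustering.n_most_variable)
    k = min(config.clustering.k, max(len(to_cluster) - 1, 1))
    labels, means = tmt.correlation_cluster(to_cluster, k)
    return tiers, labels, means


def run_all(
    config: PipelineConfig,
    table_path: str | Path,
    out_dir: str | Path,
    ppi_path: str | Path | None = None,
    orthologs_path: str | Path | None = None,
) -> Path:
    """Run the full two-screen triage on one phosphosite table.

    Fails before writing anything if an input path is missing.  The output
    directory receives: rejects.tsv, silac_calls.tsv, scatter_exp1.tsv,
    motif_enrichment.tsv, tmt_tiers.tsv, clusters.tsv, cluster_means.tsv,
    shortlist.tsv, shortlist_audit.tsv, array_design.tsv, config_used.yaml
    and provenance.yaml.
    """
    table_path = Path(table_path)
    inputs = {"table": table_path}
    if ppi_path is not None:
        inputs["ppi"] = Path(ppi_path)
    if orthologs_path is not None:
        inputs["orthologs"] = Path(orthologs_path)
    for name, p in inputs.items():
        if not p.is_file():
            raise PipelineError(f"input {name} not found: {p}")

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    table = io.read_phosphosite_table(table_path)
    io.write_results(table.rejects, out / "rejects.tsv")
    sites = io.apply_localization_filter(table.sites, config.localization_min_prob)

    # SILAC screen
    calls = silac_stage(sites, config)
    the_motif = motif_mod.parse_motif(config.motif)
    calls["motif_match"] = motif_mod.match_windows(the_motif, sites["window"])
    io.write_results(calls, out / "silac_calls.tsv")
    io.write_results(silac.scatter_table(sites, 1), out / "scatter_exp1.tsv")

    # consensus-logo matrix: depleted foreground vs all detected background
    depleted_windows = sites.loc[
        sites["site_id"].isin(calls.loc[calls["combined_depleted"], "site_id"]), "window"
    ]
    if len(depleted_windows):
        matrix = motif_mod.enrichment_matrix(list(depleted_windows), list(sites["window"]))
        matrix.to_csv(out / "motif_enrichment.tsv", sep="\t", lineterminator="\n")

    # TMT screen
    tiers, labels, means = tmt_stage(sites, config)
    io.write_results(tiers, out / "tmt_tiers.tsv")
    io.write_results(labels, out / "clusters.tsv")
    means.to_csv(out / "cluster_means.tsv", sep="\t", lineterminator="\n")

    # cross-reference and shortlist
    entries = shortlist_mod.crossref(
        calls,
        tiers,
        how="outer",
        manual_include=config.curation.manual_include,
        manual_exclude=config.curation.manual_exclude,
    )
    entries = entries.drop(columns=["gene"], errors="ignore").merge(
        sites[["site_id", "gene", "window", "residue", "position"]], on="site_id", how="left"
    )
    orthologs = None
    if orthologs_path is not None:
        orthologs = io.read_ortholog_table(orthologs_path)
        entries = shortlist_mod.apply_conservation_filter(
            entries, orthologs, config.conservation.min_identity
        )
    if ppi_path is not None:
        graph = io.read_edge_list(ppi_path)
        entries = shortlist_mod.annotate_ppi(entries, graph)

    entries = shortlist_mod.emit_shortlist(
        entries, out / "shortlist.tsv", out / "shortlist_audit.tsv"
    )
    design = shortlist_mod.design_table(
        entries, orthologs, config.curation.control_peptides
    )
    design.to_csv(out / "array_design.tsv", sep="\t", index=False, lineterminator="\n")

    # provenance
    save_config(config, out / "config_used.yaml")
    provenance = {
        "config_hash": config_hash(config),
        "phosphotriage_version": __version__,
        "inputs": {name: _sha256(p) for name, p in inputs.items()},
        "generator_seed": config.generator.seed,
        "thresholds": {
            "silac": config_to_dict(config)["silac"],
            "tmt": config_to_dict(config)["tmt"],
            "localization_min_prob": config.localization_min_prob,
            "conservation_min_identity": config.conservation.min_identity,
        },
    }
    with open(out / "provenance.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(provenance, fh, sort_keys=True)
    return out
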