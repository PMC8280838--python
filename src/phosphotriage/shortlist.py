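"""Cross-screen shortlist assembly and peptide-array design.

The SILAC depletion calls and TMT triage tiers are joined on site
identity; a site is shortlisted when it is depleted in the combined SILAC
screen *and* reaches a TMT tier (primary or similarity), or when it is
manually included with a documented reason.  Shortlisted sites are then
annotated with cross-species window conservation (low-conservation sites
are removed), network proximity to the kinase anchors, and the
peptide-array variants used for in vitro confirmation: the wild-type
15-mer, the single phosphoacceptor alanine mutant, the total S/T-to-A
mutant when further phosphoacceptors are present, and the murine sequence
when it diverges from the human one.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .io import CENTER_INDEX, PAD, WINDOW_LENGTH

ACCEPTED_TIERS = ("primary", "similarity_only")
DEFAULT_ANCHORS = ("ULK1", "ULK2")

VARIANT_LABELS = ("WT", "single_SA", "total_STA", "murine")


def crossref(
    silac_calls: pd.DataFrame,
    tmt_tiers: pd.DataFrame,
    how: str = "outer",
    manual_include: Iterable[str] = (),
    manual_exclude: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Join the two screens on site_id and apply the shortlist rule.

    Shortlist rule: (combined_depleted and tier in {primary,
    similarity_only}) or manual inclusion; manual exclusion dominates.
    Every decision records the rule that fired in ``rule``.
    Duplicate site_ids within either table are an error.
    """
    if how not in ("inner", "left", "outer"):
        raise ValueError("how must be inner, left or outer")
    for name, table in (("silac", silac_calls), ("tmt", tmt_tiers)):
        dup = table["site_id"].duplicated()
        if dup.any():
            raise ValueError(
                f"duplicate site_id in {name} table: {table.loc[dup, 'site_id'].iloc[0]}"
            )

    merged = silac_calls.merge(tmt_tiers, on="site_id", how=how, sort=True)
    merged["combined_depleted"] = (
        merged["combined_depleted"].fillna(False).astype(bool)
        if "combined_depleted" in merged
        else False
    )
    merged["tier"] = merged["tier"].fillna("absent") if "tier" in merged else "absent"

    include = set(manual_include)
    exclude = dict(manual_exclude or {})

    rules = []
    shortlisted = []
    for sid, depleted, tier in zip(
        merged["site_id"], merged["combined_depleted"], merged["tier"]
    ):
        if sid in exclude:
            rules.append(f"excluded:manual:{exclude[sid]}")
            shortlisted.append(False)
        elif depleted and tier in ACCEPTED_TIERS:
            rules.append("included:both_screens")
            shortlisted.append(True)
        elif sid in include:
            rules.append("included:manual")
            shortlisted.append(True)
        elif not depleted:
            rules.append("excluded:not_depleted")
            shortlisted.append(False)
        else:
            rules.append(f"excluded:tier_{tier}")
            shortlisted.append(False)
    merged["shortlisted"] = shortlisted
    merged["rule"] = rules
    return merged.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Conservation


def conservation_identity(window_a: str, window_b: str) -> float:
    """Fraction of aligned, non-pad positions at which the windows agree.

    Positions where either window carries the terminal pad character are
    excluded from numerator and denominator; symmetric in its arguments.
    """
    if len(window_a) != WINDOW_LENGTH or len(window_b) != WINDOW_LENGTH:
        raise ValueError("both windows must have length 15")
    compared = matched = 0
    for a, b in zip(window_a, window_b):
        if a == PAD or b == PAD:
            continue
        compared += 1
        matched += a == b
    if compared == 0:
        raise ValueError("no comparable (non-pad) positions")
    return matched / compared


def conservation_filter(
    murine_window: str, human_window: str, min_identity: float
) -> tuple[bool, float]:
    """(keep, identity) for one ortholog window pair.

    Drops when identity falls below ``min_identity`` or when the human
    window has lost the central phosphoacceptor (no S/T at centre).
    """
    identity = conservation_identity(murine_window, human_window)
    if human_window[CENTER_INDEX] not in ("S", "T"):
        return False, identity
    return identity >= min_identity, identity


def apply_conservation_filter(
    entries: pd.DataFrame, orthologs: pd.DataFrame, min_identity: float = 0.6
) -> pd.DataFrame:
    """Annotate entries with conservation and demote low-conservation sites.

    Sites without an ortholog window pair keep NaN identity and are left
    untouched (conservation unknown is not evidence against).
    """
    pairs = orthologs.set_index("site_id")
    identities = []
    keeps = []
    for sid in entries["site_id"]:
        if sid not in pairs.index:
            identities.append(math.nan)
            keeps.append(True)
            continue
        row = pairs.loc[sid]
        keep, ident = conservation_filter(
            row["window_mouse"], row["window_human"], min_identity
        )
        identities.append(ident)
        keeps.append(keep)
    out = entries.copy()
    out["conservation_identity"] = identities
    dropped = out["shortlisted"] & ~pd.Series(keeps, index=out.index)
    out.loc[dropped, "shortlisted"] = False
    out.loc[dropped, "rule"] = "excluded:low_conservation"
    return out


# ---------------------------------------------------------------------------
# Network proximity


def ppi_distance(
    graph: nx.Graph, anchors: Sequence[str] = DEFAULT_ANCHORS, target: str | None = None
) -> float:
    """Unweighted shortest-path distance from ``target`` to the nearest anchor.

    Breadth-first semantics via networkx; absent targets or anchors give
    ``inf``.  Annotation only -- never used as a hard filter.
    """
    if target is None:
        raise ValueError("target symbol required")
    target = target.upper()
    best = math.inf
    for anchor in anchors:
        anchor = anchor.upper()
        if anchor not in graph or target not in graph:
            continue
        try:
            best = min(best, nx.shortest_path_length(graph, anchor, target))
        except nx.NetworkXNoPath:
            continue
    return best


def annotate_ppi(
    entries: pd.DataFrame, graph: nx.Graph, anchors: Sequence[str] = DEFAULT_ANCHORS
) -> pd.DataFrame:
    """Add ppi_distance (inf -> NaN in the table) and a within-2-nodes flag."""
    distances = [
        ppi_distance(graph, anchors, gene) if isinstance(gene, str) else math.inf
        for gene in entries["gene"]
    ]
    out = entries.copy()
    out["ppi_distance"] = [d if math.isfinite(d) else math.nan for d in distances]
    out["ppi_within_2"] = [math.isfinite(d) and d <= 2 for d in distances]
    return out


# ---------------------------------------------------------------------------
# Peptide-array design


def design_peptide_variants(
    window: str, murine_window: str | None = None
) -> list[tuple[str, str]]:
    """Peptide variants for the in vitro kinase array, up to four per site.

    WT:        the window as given (human sequence by convention).
    single_SA: centre phosphoacceptor mutated to alanine.
    total_STA: every S/T (centre included) mutated to alanine; emitted only
               when the window carries S/T beyond the centre, otherwise it
               would duplicate single_SA.
    murine:    the murine window, only when it differs from ``window``.
    """
    if len(window) != WINDOW_LENGTH:
        raise ValueError("window must have length 15")
    center = window[CENTER_INDEX]
    if center not in ("S", "T"):
        raise ValueError(f"centre residue must be S or T, got {center!r}")

    variants = [("WT", window)]
    single = window[:CENTER_INDEX] + "A" + window[CENTER_INDEX + 1 :]
    variants.append(("single_SA", single))

    flanks = window[:CENTER_INDEX] + window[CENTER_INDEX + 1 :]
    if any(c in ("S", "T") for c in flanks):
        total = "".join("A" if c in ("S", "T") else c for c in window)
        variants.append(("total_STA", total))

    if murine_window is not None and murine_window != window:
        if len(murine_window) != WINDOW_LENGTH:
            raise ValueError("murine window must have length 15")
        variants.append(("murine", murine_window))
    return variants


def design_table(
    entries: pd.DataFrame,
    orthologs: pd.DataFrame | None = None,
    control_peptides: Sequence[Mapping[str, str]] = (),
) -> pd.DataFrame:
    """Array design for all shortlisted entries plus configured controls.

    The human ortholog window (when available) is the primary sequence,
    with the murine screen window as the divergent variant; otherwise the
    screen window stands alone.  Control peptides come from configuration
    -- validated reference substrates are appended, never synthesized.
    """
    pairs = orthologs.set_index("site_id") if orthologs is not None else None
    rows = []
    for _, entry in entries.loc[entries["shortlisted"]].iterrows():
        sid = entry["site_id"]
        window = entry["window"]
        murine = None
        if pairs is not None and sid in pairs.index:
            human = pairs.loc[sid, "window_human"]
            if human[CENTER_INDEX] in ("S", "T"):
                murine = pairs.loc[sid, "window_mouse"]
                window = human
        for label, seq in design_peptide_variants(window, murine):
            rows.append({"site_id": sid, "variant": label, "sequence": seq})
    for ctrl in control_peptides:
        rows.append(
            {
                "site_id": ctrl["label"],
                "variant": "control",
                "sequence": ctrl["sequence"],
            }
        )
    return pd.DataFrame(rows, columns=["site_id", "variant", "sequence"])


def emit_shortlist(entries: pd.DataFrame, path, audit_path=None) -> pd.DataFrame:
    """Write the shortlist TSV (shortlisted rows) and the full audit log.

    Reruns on identical inputs are byte-identical: rows are sorted by
    site_id and column order is fixed by the writer.
    """
    from .io import write_results

    entries = entries.sort_values("site_id", kind="mergesort").reset_index(drop=True)
    write_results(entries.loc[entries["shortlisted"]], path)
    if audit_path is not None:
        write_results(entries, audit_path)
    return entries
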