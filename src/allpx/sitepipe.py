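"""Site-level pipeline plumbing.

Target-decoy PSM FDR, removal of C-terminal pLys/pArg artefacts
(trypsin cannot cleave after a phosphorylated Lys/Arg, so such calls
are suspect), peptide-to-protein site mapping, unique-site aggregation
at the standard localisation-score threshold classes, and two-pass
database reduction.

Coordinates are 1-based inclusive throughout the public surface
(protein positions as in site nomenclature like "His 490"); Leu and Ile
are distinct; peptide-to-protein matching is exact substring.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .isoforms import PhosphoIsoform

#: Localisation-score threshold classes used for site reporting.
THRESHOLD_CLASSES = (0.0, 0.75, 0.90, 0.99)


def compute_fdr(psms: pd.DataFrame, score_column: str = "search_score",
                decoy_column: str = "is_decoy") -> pd.DataFrame:
    """Target-decoy running FDR and monotone q-values.

    PSMs are sorted by decreasing search score; the running FDR at each
    rank is #decoys / #targets at or above that score, and the q-value
    is the monotone minimum taken from the bottom of the list upward.
    Returns a copy sorted by score with ``q_value`` added.
    """
    if not psms[~psms[decoy_column]].shape[0]:
        raise ValueError("no target PSMs present")
    df = psms.sort_values(score_column, ascending=False, kind="stable").copy()
    n_decoy = df[decoy_column].cumsum()
    n_target = (~df[decoy_column]).cumsum()
    fdr = (n_decoy / n_target.clip(lower=1)).clip(upper=1.0)
    df["q_value"] = fdr[::-1].cummin()[::-1]
    return df


def cterm_filter(site_calls: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop pLys/pArg calls localised to the peptide C-terminus.

    Requires columns ``residue``, ``peptide`` and ``peptide_position``.
    Returns (retained calls, removal log with per-residue counts).
    The rule touches K/R only; C-terminal pSer etc. are retained.
    """
    at_cterm = site_calls["peptide_position"] == site_calls["peptide"].str.len()
    removed_mask = site_calls["residue"].isin(["K", "R"]) & at_cterm
    removed = site_calls[removed_mask]
    log = (
        removed["residue"].value_counts().rename("n_removed").to_frame()
        .reindex(["K", "R"], fill_value=0)
    )
    total = site_calls["residue"].isin(["K", "R"]).groupby(site_calls["residue"]).size()
    log["n_total"] = total.reindex(["K", "R"], fill_value=0)
    log["fraction_removed"] = (log["n_removed"] / log["n_total"].clip(lower=1)).round(4)
    return site_calls[~removed_mask].copy(), log


def map_sites(
    peptide: str,
    isoform: PhosphoIsoform,
    protein_sequence: str,
    protein_accession: str,
    *,
    score: float = float("nan"),
    scan_id: str | None = None,
) -> pd.DataFrame:
    """Map an isoform's phosphosites onto 1-based protein coordinates.

    Every occurrence of the peptide in the protein is emitted; multiple
    occurrences are flagged ambiguous.  Raises if the peptide does not
    occur in the protein.
    """
    if isoform.sequence != peptide:
        raise ValueError("isoform sequence does not match the peptide")
    offsets = []
    start = protein_sequence.find(peptide)
    while start != -1:
        offsets.append(start)
        start = protein_sequence.find(peptide, start + 1)
    if not offsets:
        raise ValueError(f"peptide {peptide!r} not found in protein {protein_accession}")
    ambiguous = len(offsets) > 1
    rows = []
    for off in offsets:
        for pep_pos, residue in isoform.sites():
            rows.append({
                "protein": protein_accession,
                "position": off + pep_pos,  # 0-based offset + 1-based pep pos
                "residue": residue,
                "score": score,
                "peptide": peptide,
                "peptide_position": pep_pos,
                "c_terminal": pep_pos == len(peptide),
                "ambiguous": ambiguous,
                "scan_id": scan_id,
            })
    return pd.DataFrame(rows)


def aggregate_unique_sites(
    site_calls: pd.DataFrame,
    threshold_classes: Sequence[float] = THRESHOLD_CLASSES,
) -> pd.DataFrame:
    """Unique-site counts per residue class at each score threshold.

    A unique site is one (protein, position); its score is the maximum
    over supporting PSMs.  Returns residues x thresholds counts (columns
    labelled ``ge_<t>``); counts are non-increasing across thresholds.
    """
    thresholds = sorted(threshold_classes)
    if site_calls.empty:
        return pd.DataFrame(columns=[f"ge_{t:g}" for t in thresholds])
    best = (
        site_calls.groupby(["protein", "position", "residue"], as_index=False)["score"]
        .max()
    )
    out = {}
    for t in thresholds:
        out[f"ge_{t:g}"] = best[best["score"] >= t]["residue"].value_counts()
    table = pd.DataFrame(out).fillna(0).astype(int).sort_index()
    table.index.name = "residue"
    return table


def reduce_database(
    first_pass_accessions: Iterable[str],
    fasta: Mapping[str, str],
) -> dict[str, str]:
    """Subset a FASTA map to the accessions of a first-pass search.

    Order-preserving and duplicate-collapsing; unknown accessions are
    skipped with a warning (count reported in the warning message).
    """
    out: dict[str, str] = {}
    missing = []
    for acc in first_pass_accessions:
        if acc in out:
            continue
        if acc not in fasta:
            missing.append(acc)
            continue
        out[acc] = fasta[acc]
    if missing:
        warnings.warn(f"{len(missing)} accession(s) absent from FASTA, skipped: "
                      f"{missing[:5]}{'...' if len(missing) > 5 else ''}")
    return out
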