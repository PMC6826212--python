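"""Decoy-amino-acid false localisation rate (FLR) estimation.

Alanine cannot be phosphorylated, so when a search nevertheless allows
variable "phosphorylation" of Ala, every apparent pAla site is a random
mislocalisation.  Normalising the decoy count by relative residue
frequency gives a residue-specific FLR:

    FLR_X(t) = min(1, [N_A(t) * f_X / f_A] / N_X(t))

where N_X(t) is the number of unique sites on residue X localised at
score >= t, and f_X the relative frequency of X in the chosen basis
(by default the identified-peptide pool — the population the random
assignment draws from).  The estimated number of true-positive sites is
round(N_X * (1 − FLR_X)), half-up.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

DECOY_RESIDUE = "A"

#: Columns a site-call table must provide.
SITECALL_COLUMNS = ("protein", "position", "residue", "score")


def _round_half_up(x: float) -> int:
    import math
    return int(math.floor(x + 0.5))


def residue_frequencies(
    sequences: Iterable[str],
    basis_label: str = "identified-peptides",
) -> pd.DataFrame:
    """Residue occurrence counts and relative frequencies over ``sequences``.

    Returns a DataFrame indexed by residue with columns ``count`` and
    ``frequency``; ``.attrs['basis']`` records the basis label
    (identified-peptides vs database composition).
    """
    counts: dict[str, int] = {}
    total = 0
    for seq in sequences:
        for ch in seq:
            counts[ch] = counts.get(ch, 0) + 1
            total += 1
    if total == 0:
        raise ValueError("cannot compute residue frequencies from empty input")
    df = pd.DataFrame(
        {"count": pd.Series(counts, dtype=int)}
    ).sort_index()
    df["frequency"] = df["count"] / total
    df.attrs["basis"] = basis_label
    return df


def unique_sites(site_calls: pd.DataFrame, threshold: float = 0.0,
                 exclude_cterm_kr: bool = False) -> pd.DataFrame:
    """Collapse site calls to unique (protein, position) sites.

    A site's score is the maximum localisation score over its
    supporting PSMs.  With ``exclude_cterm_kr``, pLys/pArg calls at the
    peptide C-terminus (column ``c_terminal``) are dropped first.
    """
    df = site_calls
    if exclude_cterm_kr and "c_terminal" in df.columns:
        df = df[~(df["residue"].isin(["K", "R"]) & df["c_terminal"])]
    agg = (
        df.groupby(["protein", "position", "residue"], as_index=False)["score"]
        .max()
    )
    return agg[agg["score"] >= threshold]


def estimate_flr(
    site_calls: pd.DataFrame,
    frequencies: pd.DataFrame | Mapping[str, float],
    threshold: float,
    decoy_residue: str = DECOY_RESIDUE,
    *,
    exclude_cterm_kr: bool = False,
) -> pd.DataFrame:
    """Residue-specific FLR and true-positive estimates at one threshold.

    Returns a DataFrame indexed by residue class with columns
    ``threshold, n_sites, n_decoy, f_x, f_decoy, flr, tp``.  Residues
    with no sites at the threshold are absent (FLR undefined, never
    reported as zero).  The decoy residue's own FLR is identically 1.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    freq = (frequencies["frequency"] if isinstance(frequencies, pd.DataFrame)
            else pd.Series(dict(frequencies), dtype=float))
    if decoy_residue not in freq.index or freq[decoy_residue] <= 0:
        raise ValueError(f"decoy residue {decoy_residue!r} has zero/absent frequency")

    sites = unique_sites(site_calls, threshold, exclude_cterm_kr=exclude_cterm_kr)
    counts = sites["residue"].value_counts()
    n_decoy = int(counts.get(decoy_residue, 0))
    f_decoy = float(freq[decoy_residue])

    rows = []
    for residue, n_x in counts.sort_index().items():
        if residue not in freq.index:
            raise KeyError(f"no frequency available for residue {residue!r}")
        f_x = float(freq[residue])
        flr = min(1.0, (n_decoy * f_x / f_decoy) / n_x)
        rows.append({
            "residue": residue,
            "threshold": threshold,
            "n_sites": int(n_x),
            "n_decoy": n_decoy,
            "f_x": f_x,
            "f_decoy": f_decoy,
            "flr": flr,
            "tp": true_positives(int(n_x), flr),
        })
    return pd.DataFrame(rows).set_index("residue")


def true_positives(n_sites: int, flr: float) -> int:
    """Estimated true-positive site count: round(n * (1 − FLR)), half-up."""
    if not 0.0 <= flr <= 1.0:
        raise ValueError("flr must lie in [0, 1]")
    return _round_half_up(n_sites * (1.0 - flr))


def overlap_flr(matched: int, total: int) -> tuple[float, float]:
    """Overlap with an external site catalogue and the implied maximum FLR.

    Returns (overlap %, maximum FLR %) where maximum FLR = 100 − overlap:
    sites absent from prior catalogues are at worst all mislocalised.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= matched <= total:
        raise ValueError("matched must lie in [0, total]")
    overlap = 100.0 * matched / total
    return overlap, 100.0 - overlap


def abundance_ratio(tp_by_residue: Mapping[str, float]) -> dict[str, float]:
    """True-positive counts expressed as ratios normalised to pTyr = 1.0."""
    if "Y" not in tp_by_residue or tp_by_residue["Y"] <= 0:
        raise ValueError("a positive pTyr true-positive count is required")
    ref = float(tp_by_residue["Y"])
    return {res: round(tp / ref, 1) for res, tp in tp_by_residue.items()}
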