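"""End-to-end run: localise -> filter -> map -> aggregate -> FLR -> NL -> motifs.

The pipeline consumes either a simulated corpus (when no input paths
are given) or MGF spectra plus a PSM table (``scan_id, peptide,
protein, k_phospho``) and a FASTA database.  Outputs are tab-separated
tables plus a run log recording the seed, parameters and in/out counts
per stage, so the identification funnel can be read off the log.
All outputs are bit-reproducible given (config, seed, inputs).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import decoyflr, io as _io, motifs as _motifs, nlanalysis, sitepipe, synthdata
from .isoforms import ALL_PX, ModifiableAlphabet
from .localization import Spectrum, score_sites

THRESHOLDS = (0.75, 0.90, 0.99)
FDR_LEVELS = (0.01, 0.05)


@dataclass
class RunConfig:
    """Paths and analysis constants for one pipeline run."""

    out_dir: str
    seed: int = 0
    mgf: str | None = None
    psm_table: str | None = None
    fasta: str | None = None
    tolerance: float = 0.5
    depth: int = 8
    thresholds: tuple[float, ...] = THRESHOLDS
    fdr_levels: tuple[float, ...] = FDR_LEVELS
    decoy_active: bool = True
    n_spectra: int = 500           # simulated corpus size when no inputs given
    scramble_rate: float = 0.0
    ambiguous_fraction: float = 0.05
    motif_min_occurrences: int = 20
    motif_p_threshold: float = 1e-6
    verbosity: int = 1

    def __post_init__(self):
        for t in self.thresholds:
            if not 0.0 <= t <= 1.0:
                raise ValueError("thresholds must lie in [0, 1]")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns a dict of the principal tables."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str):
        log_lines.append(msg)
        if config.verbosity:
            print(msg)

    t0 = time.time()
    alphabet = ALL_PX.decoy() if config.decoy_active else ALL_PX

    # ---- inputs -----------------------------------------------------
    if config.mgf and config.psm_table and config.fasta:
        proteins = _io.read_fasta(config.fasta)
        spectra = list(_io.read_mgf(config.mgf))
        psms = _io.read_table(config.psm_table)
        log(f"inputs: {len(spectra)} spectra, {len(psms)} PSMs, "
            f"{len(proteins)} proteins (loaded)")
    elif config.mgf or config.psm_table or config.fasta:
        raise ValueError("mgf, psm_table and fasta must be given together")
    else:
        sim = synthdata.SimulationConfig(
            seed=config.seed,
            n_spectra=config.n_spectra,
            decoy_active=config.decoy_active,
            scramble_rate=config.scramble_rate,
            ambiguous_fraction=config.ambiguous_fraction,
        )
        rng_proteins = synthdata.random_proteins(
            np.random.default_rng(config.seed), sim.n_proteins, sim.protein_length)
        sim.proteins = rng_proteins
        proteins = rng_proteins
        spectra, truth = synthdata.simulate_spectra(sim)
        psms = truth.rename(columns={"peptide": "peptide"})[
            ["scan_id", "peptide", "protein"]].copy()
        psms["k_phospho"] = 1
        _io.write_table(truth, out / "truth.tsv")
        _io.write_mgf(spectra, out / "corpus.mgf")
        log(f"inputs: simulated {len(spectra)} spectra from "
            f"{len(proteins)} proteins (seed={config.seed})")

    by_scan = {s.scan_id: s for s in spectra}

    # ---- localise ---------------------------------------------------
    rows = []
    for psm in psms.itertuples(index=False):
        spec = by_scan.get(psm.scan_id)
        if spec is None:
            raise RuntimeError(f"stage localize: no spectrum for scan {psm.scan_id}")
        k = int(getattr(psm, "k_phospho", 1))
        res = score_sites(spec, psm.peptide, k, alphabet,
                          tolerance=config.tolerance, depth=config.depth)
        best = res.best_isoform()
        for pos, residue, prob in res.best_sites():
            rows.append({
                "scan_id": psm.scan_id, "peptide": psm.peptide,
                "protein": psm.protein, "isoform": best.annotated(),
                "peptide_position": pos, "residue": residue,
                "probability": prob,
                "matched_ions": res.matched_counts[best],
                "rank_delta": res.rank1_rank2_ion_delta,
            })
    psm_sites = pd.DataFrame(rows)
    _io.write_table(psm_sites, out / "psm_sites.tsv")
    log(f"localize: {len(psms)} PSMs -> {len(psm_sites)} site calls")

    # ---- map to proteins -------------------------------------------
    mapped = []
    for r in psm_sites.itertuples(index=False):
        seq = proteins[r.protein]
        off = seq.find(r.peptide)
        if off < 0:
            raise RuntimeError(f"stage map: peptide {r.peptide!r} absent from {r.protein}")
        mapped.append({
            "protein": r.protein, "position": off + r.peptide_position,
            "residue": r.residue, "score": r.probability,
            "peptide": r.peptide, "peptide_position": r.peptide_position,
            "c_terminal": r.peptide_position == len(r.peptide),
            "scan_id": r.scan_id,
        })
    site_calls = pd.DataFrame(mapped)
    log(f"map: {len(site_calls)} site calls mapped to protein coordinates")

    # ---- C-terminal pLys/pArg filter -------------------------------
    filtered, removal_log = sitepipe.cterm_filter(site_calls)
    _io.write_table(removal_log, out / "cterm_removals.tsv", index=True)
    log(f"cterm_filter: {len(site_calls)} -> {len(filtered)} calls "
        f"({len(site_calls) - len(filtered)} C-terminal K/R removed)")

    # ---- aggregate unique sites ------------------------------------
    unique_counts = sitepipe.aggregate_unique_sites(
        filtered, (0.0,) + tuple(config.thresholds))
    _io.write_table(unique_counts, out / "unique_sites.tsv", index=True)
    log(f"aggregate: unique sites per class\n{unique_counts.to_string()}")

    # ---- decoy FLR --------------------------------------------------
    flr_tables = []
    freqs = decoyflr.residue_frequencies(
        filtered["peptide"].drop_duplicates(), "identified-peptides")
    for t in config.thresholds:
        try:
            tab = decoyflr.estimate_flr(filtered, freqs, t)
        except ValueError as exc:
            log(f"flr: threshold {t}: skipped ({exc})")
            continue
        tab = tab.reset_index()
        flr_tables.append(tab)
    flr = pd.concat(flr_tables, ignore_index=True) if flr_tables else pd.DataFrame()
    _io.write_table(flr, out / "flr.tsv")
    log(f"flr: {len(flr)} residue/threshold rows")

    # ---- neutral-loss diagnostics ----------------------------------
    best_residue = (
        filtered[filtered["score"] >= 0.90]
        .sort_values("score").groupby("scan_id")["residue"].last().to_dict()
    )
    nl_rows = []
    results = []
    for s in spectra:
        for cutoff in (2.0, 5.0, 10.0):
            tr = nlanalysis.triplet_score(s, config.tolerance, cutoff)
            if cutoff == 5.0:
                results.append(tr)
            nl_rows.append({
                "scan_id": s.scan_id, "cutoff_pct": cutoff,
                **{f"d{nlanalysis.LOSS_NOMINAL[k]}": v for k, v in tr.flags.items()},
                "triplet_score": tr.triplet_score,
            })
    _io.write_table(pd.DataFrame(nl_rows), out / "triplet_scores.tsv")
    score_pct, combos = nlanalysis.triplet_summary(results, best_residue)
    _io.write_table(score_pct, out / "triplet_summary.tsv", index=True)
    _io.write_table(combos, out / "triplet_combinations.tsv", index=True)
    log(f"nl: {len(spectra)} scans scored; {len(score_pct)} residue classes summarised")

    # ---- motifs -----------------------------------------------------
    best_sites = decoyflr.unique_sites(filtered, 0.99)
    motif_rows = []
    for residue in sorted(best_sites["residue"].unique()):
        fg_sites = best_sites[best_sites["residue"] == residue]
        fg = _motifs.extract_windows(fg_sites, proteins)
        bg_sites = pd.DataFrame([
            {"protein": acc, "position": i + 1, "residue": residue}
            for acc, seq in proteins.items()
            for i, ch in enumerate(seq) if ch == residue
        ])
        bg = _motifs.extract_windows(bg_sites, proteins) if len(bg_sites) else []
        if len(bg) < len(fg):
            continue
        for m in _motifs.motif_enrich(fg, bg, config.motif_min_occurrences,
                                      config.motif_p_threshold):
            motif_rows.append({
                "residue": residue, "pattern": m.pattern(),
                "fg_matches": m.foreground_matches, "fg_size": m.foreground_size,
                "bg_matches": m.background_matches, "bg_size": m.background_size,
                "fold": m.fold_enrichment, "p_value": m.p_value,
            })
    _io.write_table(pd.DataFrame(motif_rows), out / "motifs.tsv")
    log(f"motifs: {len(motif_rows)} enriched patterns")

    if config.verbosity:
        print(f"done in {time.time() - t0:.1f} s")
    with open(out / "run_log.txt", "w", newline="\n") as fh:
        fh.write(f"allpx run (seed={config.seed}, tolerance={config.tolerance}, "
                 f"depth={config.depth}, thresholds={config.thresholds})\n")
        fh.write("\n".join(log_lines) + "\n")

    return {
        "psm_sites": psm_sites, "site_calls": filtered,
        "unique_sites": unique_counts, "flr": flr,
        "triplet_summary": score_pct, "motifs": pd.DataFrame(motif_rows),
    }
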