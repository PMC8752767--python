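"""End-to-end pipeline: simulate -> scan -> rank -> enrich -> apd -> rp.

Drives every stage of the analysis from one configuration mapping, writing
the declared TSV/CSV outputs into one directory.  Used by the CLI
``pipeline`` subcommand; all heavy lifting stays in the library modules.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import io as cio
from .enrichment import GeneSet, enrichment_to_frame, fisher_enrichment, target_shift_test
from .refractory import RPConfig, build_schedule, refractory_period
from .simulate import (
    APWaveformParams,
    DESimParams,
    ForceSimParams,
    UTRSimParams,
    random_family_pool,
    simulate_ap_trace,
    simulate_de_table,
    simulate_expression,
    simulate_force_trace,
    simulate_utrs,
)
from .targetome import (
    SeedFamily,
    count_matrix,
    filter_expressed_genes,
    rank_families,
    top_n_entities,
)
from .traces import APConfig, analyze_cell

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict[str, Any] = {
    "utrs": {"n_genes": 20, "utr_length": 400, "n_families": 8, "sites_per_gene_max": 3},
    "expression": {"n_entities": 200, "n_expressed_in_both": 46, "n_top": 100},
    "gene_expression": {"tpm_threshold": 1.0},
    "enrichment": {"n_terms": 5, "term_size": 8},
    "ap": {
        "baseline": 1.0, "amplitude": 1.0, "upstroke_duration": 0.0,
        "plateau_duration": 200.0, "repolarization_duration": 200.0,
        "beat_interval": 640.0, "n_beats": 10, "sampling_interval": 1.0,
        "noise_sd": 0.02, "drift_per_s": 0.005,
    },
    "rp": {"true_rp": 400.0, "step": 50.0, "noise_sd": 0.02, "block_duration": 20.0},
    "de": {"n_genes": 1100, "n_targets": 100, "target_shift": -0.5, "sd_log2fc": 0.2},
}


def _merged(user: Mapping[str, Any] | None) -> dict[str, Any]:
    cfg = {k: dict(v) for k, v in DEFAULT_CONFIG.items()}
    for section, values in (user or {}).items():
        cfg.setdefault(section, {}).update(values or {})
    return cfg


def run_pipeline(config: Mapping[str, Any] | None, seed: int, outdir: str | Path) -> dict[str, Any]:
    """Run the full desk-scale analysis; returns a summary of key results.

    Writes, under ``outdir``: UTR and planted-site files, expression
    tables, the site table, binding-site count matrix and family ranking,
    enrichment results, the AP trace with its per-cell summary, and the
    force trace with the refractory-period result.
    """
    cfg = _merged(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    summary: dict[str, Any] = {"seed": seed}

    # --- 1. synthetic UTR set with planted sites, scanned and ranked
    ucfg = cfg["utrs"]
    pool = random_family_pool(ucfg["n_families"], rng_seed=int(rng.integers(2**31)))
    fam_ids = sorted(pool)
    planted: dict[str, list[tuple[str, str]]] = {}
    site_types = ["8mer", "7mer-m8", "7mer-A1"]
    for g in range(ucfg["n_genes"]):
        k = int(rng.integers(0, ucfg["sites_per_gene_max"] + 1))
        planted[f"gene{g:03d}"] = [
            (fam_ids[int(rng.integers(len(fam_ids)))], site_types[int(rng.integers(3))])
            for _ in range(k)
        ]
    params = UTRSimParams(
        n_genes=ucfg["n_genes"], utr_length=ucfg["utr_length"],
        family_pool=pool, planted_sites=planted,
        rng_seed=int(rng.integers(2**31)),
    )
    utrs, truth = simulate_utrs(params)
    cio.write_fasta([(u.gene_id, u.sequence) for u in utrs], out / "utrs.fasta")
    cio.write_table(truth, out / "planted_sites.tsv")

    families = [SeedFamily(family_id=f, seed=s) for f, s in sorted(pool.items())]
    matrix = count_matrix(utrs, families)
    cio.write_sites(matrix.sites, out / "sites.tsv")
    cio.write_matrix(matrix, out / "site_count_matrix.tsv")
    ranking = rank_families(matrix)
    cio.write_table(ranking, out / "family_ranking.tsv")
    summary["n_sites_found"] = int(matrix.counts.to_numpy().sum())
    summary["n_sites_planted"] = int(len(truth))
    summary["top_family"] = ranking.iloc[0]["family_id"] if len(ranking) else None

    # --- 2. expression gating
    ecfg = cfg["expression"]
    tab_a, tab_b = simulate_expression(
        ecfg["n_entities"], ecfg["n_expressed_in_both"],
        rng_seed=int(rng.integers(2**31)), n_top=ecfg["n_top"],
    )
    cio.write_table(tab_a, out / "mirna_expression_a.tsv")
    cio.write_table(tab_b, out / "mirna_expression_b.tsv")
    gated = top_n_entities(tab_a, tab_b, n=ecfg["n_top"])
    summary["n_gated_mirnas"] = len(gated)

    gene_expr = pd.DataFrame(
        {
            "gene_id": [u.gene_id for u in utrs],
            "tpm": rng.lognormal(1.0, 1.5, size=len(utrs)),
        }
    )
    cio.write_table(gene_expr, out / "gene_expression.tsv")
    expressed = filter_expressed_genes(
        gene_expr, threshold=cfg["gene_expression"]["tpm_threshold"]
    )
    summary["n_expressed_genes"] = len(expressed)

    # --- 3. targetome enrichment on synthetic disease terms
    ncfg = cfg["enrichment"]
    universe_ids = [u.gene_id for u in utrs]
    top_fam = ranking.iloc[0]["family_id"]
    target_genes = matrix.targeted_genes(top_fam)
    terms = []
    for t in range(ncfg["n_terms"]):
        members = rng.choice(universe_ids, size=min(ncfg["term_size"], len(universe_ids)),
                             replace=False)
        terms.append(GeneSet(f"term{t:02d}", members))
    enr = fisher_enrichment(
        GeneSet("targetome", target_genes), terms, GeneSet("universe", universe_ids)
    )
    cio.write_table(enrichment_to_frame(enr), out / "enrichment.tsv")
    summary["min_enrichment_p"] = float(min((r.p_value for r in enr), default=1.0))

    # --- 4. DE shift test on a planted table
    dcfg = cfg["de"]
    de_table, labels = simulate_de_table(
        DESimParams(
            n_genes=dcfg["n_genes"], n_targets=dcfg["n_targets"],
            target_shift=dcfg["target_shift"], sd_log2fc=dcfg["sd_log2fc"],
            rng_seed=int(rng.integers(2**31)),
        )
    )
    cio.write_table(de_table, out / "de_table.tsv")
    shift = target_shift_test(de_table, de_table["gene_id"][labels])
    summary["shift_test_p"] = shift.p_value
    summary["median_shift"] = shift.median_shift

    # --- 5. optical AP analysis
    acfg = cfg["ap"]
    ap_params = APWaveformParams(**acfg, rng_seed=int(rng.integers(2**31)))
    trace, ap_truth = simulate_ap_trace(ap_params)
    cio.write_trace_csv(trace, out / "ap_trace.csv", column="ratio")
    cell = analyze_cell(trace, APConfig())
    pd.DataFrame([cell.__dict__]).to_csv(out / "cell_summary.tsv", sep="\t", index=False)
    summary["median_apd90"] = cell.median_apd90
    summary["median_capd90"] = cell.median_capd90
    summary["true_apd90"] = float(ap_params.true_apd90)

    # --- 6. refractory period from a programmed force recording
    rcfg = cfg["rp"]
    schedule = build_schedule(step=rcfg["step"], block_duration=rcfg["block_duration"])
    force_params = ForceSimParams(
        true_rp=rcfg["true_rp"], noise_sd=rcfg["noise_sd"],
        rng_seed=int(rng.integers(2**31)),
    )
    force_trace, true_rp = simulate_force_trace(force_params, schedule)
    cio.write_force_csv(force_trace, out / "force_trace.csv", out / "stimuli.csv")
    rp_res = refractory_period(force_trace, schedule, RPConfig())
    cio.write_table(rp_res.per_block, out / "rp_blocks.tsv")
    pd.DataFrame(
        [{"rp_ms": rp_res.rp, "status": rp_res.status, "true_rp_ms": true_rp}]
    ).to_csv(out / "rp_result.tsv", sep="\t", index=False)
    summary["rp_estimate"] = rp_res.rp
    summary["rp_true"] = true_rp

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary
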