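"""End-to-end orchestration on a synthetic study, with truth-based metrics.

Runs simulate -> discover -> diffexpr -> targetscan -> netenrich and scores
the result against the study's truth tables: planted-locus recovery,
contaminant leakage, DE sensitivity / false-positive rate / sign agreement,
planted-site recovery, designed-term enrichment, and hub identification.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import diffexpr, discover, netenrich, targetscan
from .simulate import SimulationConfig, Study, simulate_study


@dataclass
class StudyRun:
    study: Study
    discovery: discover.DiscoveryResult
    expression: dict[str, pd.DataFrame]
    metrics: dict[str, float]


def run_discovery(study: Study) -> discover.DiscoveryResult:
    cfg = study.config
    fastqs = {rep: study.paths.fastq(rep) for rep in cfg.replicate_ids()}
    mirnas = [
        row.sequence
        for row in study.features[study.features["type"] == "miRNA"].itertuples(index=False)
    ]
    return discover.discover_pipeline(
        fastqs,
        study.genome,
        study.features,
        mirna_sequences=mirnas,
        rep_to_group=cfg.rep_to_group(),
    )


def run_expression(study: Study, disc: discover.DiscoveryResult) -> dict[str, pd.DataFrame]:
    cfg = study.config
    counts = disc.counts_frame()
    out = {}
    for g1, g2 in cfg.comparisons():
        spec = diffexpr.ComparisonSpec(name=f"{g1} vs {g2}", numerator=g2, denominator=g1)
        out[spec.name] = diffexpr.run_comparison(
            counts, disc.library_sizes, cfg.rep_to_group(), spec
        )
    return out


def discovery_metrics(study: Study, disc: discover.DiscoveryResult) -> dict[str, float]:
    truth_seqs = set(study.truth.loci["sequence"])
    found_seqs = {c.sequence for c in disc.candidates}
    recovered = truth_seqs & found_seqs
    contaminants = found_seqs - truth_seqs
    bias = discover.first_base_bias(disc.candidates)
    return {
        "n_candidates": len(disc.candidates),
        "n_planted_loci": len(truth_seqs),
        "locus_recovery": len(recovered) / len(truth_seqs) if truth_seqs else 1.0,
        "n_contaminant_candidates": len(contaminants),
        "first_base_c_fraction": bias["C"],
        "modal_first_base_is_c": float(max(bias, key=bias.get) == "C"),
    }


def de_metrics(study: Study, disc: discover.DiscoveryResult, expression) -> dict[str, float]:
    """Sensitivity, false-positive rate and sign agreement of the DE caller."""
    seq_to_id = {c.sequence: c.pirna_id for c in disc.candidates}
    loci = study.truth.loci
    tp = fn = fp = tn = sign_ok = sign_total = 0
    for g1, g2 in study.config.comparisons():
        comp = f"{g1} vs {g2}"
        table = expression[comp]
        for row in loci.itertuples(index=False):
            pid = seq_to_id.get(row.sequence)
            if pid is None or pid not in table.index:
                continue
            direction = table.loc[pid, "direction"]
            true_fc = getattr(row, f"log2fc_{g1}_vs_{g2}")
            if abs(true_fc) >= 1.0:
                if direction == "ns":
                    fn += 1
                else:
                    tp += 1
                    sign_total += 1
                    if (true_fc > 0) == (direction == "up"):
                        sign_ok += 1
            else:
                if direction == "ns":
                    tn += 1
                else:
                    fp += 1
    return {
        "de_sensitivity": tp / (tp + fn) if tp + fn else 1.0,
        "de_false_positive_rate": fp / (fp + tn) if fp + tn else 0.0,
        "de_sign_agreement": sign_ok / sign_total if sign_total else 1.0,
        "n_true_de_tested": tp + fn,
        "n_null_tested": fp + tn,
    }


def target_and_network_metrics(
    study: Study, disc: discover.DiscoveryResult, expression
) -> dict[str, float]:
    """Scan called DEpiRNAs against the transcripts; score site recovery,
    designed enrichment and hub identification against the truth tables."""
    seq_to_id = {c.sequence: c.pirna_id for c in disc.candidates}
    locus_to_pid = {
        row.locus_id: seq_to_id.get(row.sequence)
        for row in study.truth.loci.itertuples(index=False)
    }

    de_directions: dict[str, dict[str, str]] = {}
    de_pirnas: dict[str, str] = {}
    id_to_seq = {c.pirna_id: c.sequence for c in disc.candidates}
    for comp, table in expression.items():
        called = table[table["direction"] != "ns"]
        de_directions[comp] = dict(zip(called.index, called["direction"]))
        for pid in called.index:
            de_pirnas[pid] = id_to_seq[pid]

    params = targetscan.ScoringParams()
    hits = targetscan.scan_many(de_pirnas, study.transcripts, params)
    gated, per_pirna = targetscan.gate_targets(hits, params.energy_gate)

    # planted-site recovery among scanned (i.e. DE-called) piRNAs
    sites = study.truth.sites
    found = {(h.pirna_id, h.transcript_id, h.start) for h in gated}
    n_sites = n_recovered = 0
    for row in sites.itertuples(index=False):
        pid = locus_to_pid.get(row.locus_id)
        if pid is None or pid not in de_pirnas:
            continue
        n_sites += 1
        if (pid, row.transcript_id, row.start) in found:
            n_recovered += 1

    # term map is read back from the study's written TSV
    from .io import read_term_map

    term_map = read_term_map(study.paths.terms)
    target_genes = {h.transcript_id for h in gated}
    background = set(study.transcripts)
    enr = netenrich.enrich_terms(target_genes, background, term_map)
    designed = enr[enr["term"] == study.config.enriched_term]
    designed_p = float(designed["p_value"].iloc[0]) if len(designed) else 1.0

    network = netenrich.build_network(de_directions, gated, term_map, study.categories)
    # hub check against truth: the piRNA(s) with the most gated target genes
    # must be the one(s) with the most planted target transcripts
    truth_counts = sites.groupby("locus_id")["transcript_id"].nunique()
    truth_by_pid = {
        locus_to_pid[l]: int(c)
        for l, c in truth_counts.items()
        if locus_to_pid.get(l) in de_pirnas
    }
    hub_match = 0.0
    if truth_by_pid and len(per_pirna):
        top_truth = {p for p, c in truth_by_pid.items() if c == max(truth_by_pid.values())}
        obs = dict(zip(per_pirna["pirna_id"], per_pirna["n_target_genes"]))
        top_obs = {p for p, c in obs.items() if c == max(obs.values())}
        hub_match = float(bool(top_truth & top_obs))
    return {
        "n_de_called": len(de_pirnas),
        "n_gated_hits": len(gated),
        "planted_site_recovery": n_recovered / n_sites if n_sites else 1.0,
        "designed_enrichment_p": designed_p,
        "max_hub_targets": int(per_pirna["n_target_genes"].max()) if len(per_pirna) else 0,
        "hub_matches_truth": hub_match,
        "network_edges": network.number_of_edges(),
    }


def run_study(config: SimulationConfig, workdir: str | Path, with_targets: bool = True) -> StudyRun:
    """Simulate, analyse and score one synthetic study."""
    study = simulate_study(config, Path(workdir))
    disc = run_discovery(study)
    expression = run_expression(study, disc)
    metrics = {}
    metrics.update(discovery_metrics(study, disc))
    metrics.update(de_metrics(study, disc, expression))
    if with_targets:
        metrics.update(target_and_network_metrics(study, disc, expression))
    return StudyRun(study=study, discovery=disc, expression=expression, metrics=metrics)
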