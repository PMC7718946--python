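"""End-to-end orchestration: simulate -> classify -> GSEA -> screen -> statistics.

``run_full_analysis`` reproduces the whole analysis surface on synthetic
cohorts with planted structure: consensus MYC-high calls (with Venn counts)
in two cohorts, per-cohort enrichment of the signature panel against decoy
sets with the cross-cohort intersection at an FDR threshold, single-dose
screen hit calling, dose-response fitting and sensitivity-quartile
enrichment on a cell-line panel, and survival / subtype-association tests.
The report is a plain JSON-serializable dict; identical config + seed gives
a byte-identical serialized report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .classify import call_high_cluster, cluster_by_signature, consensus_calls
from .dataio import (
    GeneSet,
    PhenotypeLabels,
    write_drug_table,
    write_expression_matrix,
    write_gmt,
    write_phenotype,
)
from .gsea import gsea, intersect_enriched
from .screen import fit_4pl, quartile_stratify, score_single_dose_screen
from .stats import ContingencyTable2x2, SurvivalRecord, fisher_exact, logrank_test
from .synthetic import (
    CohortSimConfig,
    ScreenSimConfig,
    SyntheticCohort,
    simulate_cohort,
    simulate_dose_response,
    simulate_screen,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_full_analysis"]

REPORT_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Settings for a full synthetic run; defaults mirror the study conditions."""

    cohort_a: CohortSimConfig = field(default_factory=lambda: CohortSimConfig(n_samples=80))
    cohort_b: CohortSimConfig = field(default_factory=lambda: CohortSimConfig(n_samples=150))
    screen: ScreenSimConfig = field(default_factory=ScreenSimConfig)
    line_panel: CohortSimConfig = field(
        default_factory=lambda: CohortSimConfig(n_samples=40, frac_myc_high=0.25)
    )
    k: int = 2
    secondary_threshold: float | None = None
    n_perm: int = 1000
    weight_p: float = 1.0
    perm_type: str = "auto"
    q_threshold: float = 0.25
    quartile: float = 0.25
    n_decoy_sets: int = 20
    decoy_size: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.q_threshold < 1:
            raise ValueError("q_threshold must be in (0, 1)")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, sub in (
            ("cohort_a", CohortSimConfig),
            ("cohort_b", CohortSimConfig),
            ("screen", ScreenSimConfig),
            ("line_panel", CohortSimConfig),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-stage seeds derived from the master seed (< 2^31)."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s & 0x7FFFFFFF) for s in state]


def _stage(name: str, t0: float, **shapes) -> None:
    logger.info("stage=%s elapsed=%.2fs %s", name, time.perf_counter() - t0,
                " ".join(f"{k}={v}" for k, v in shapes.items()))


def _classify_cohort(
    cohort: SyntheticCohort, panel: list[GeneSet], k: int, secondary: float | None
):
    per_sig: dict[str, set[str]] = {}
    secondary_included: set[str] = set()
    for sig in panel:
        assignment = cluster_by_signature(cohort.expression, sig, k=k)
        high, extra = call_high_cluster(
            assignment, cohort.expression, sig, secondary_rule=secondary
        )
        per_sig[sig.name] = high
        secondary_included |= extra
    calls = consensus_calls(per_sig)
    calls.secondary_included = secondary_included
    return calls


def _precision_recall(called: set[str], truth: set[str]) -> tuple[float, float]:
    tp = len(called & truth)
    precision = tp / len(called) if called else 0.0
    recall = tp / len(truth) if truth else 0.0
    return precision, recall


def _decoy_sets(
    gene_ids: list[str], n_sets: int, size: int, seed: int, exclude: set[str] = frozenset()
) -> list[GeneSet]:
    """Random gene sets standing in for unrelated pathways (planted genes excluded)."""
    pool = [g for g in gene_ids if g not in exclude]
    rng = np.random.default_rng(seed)
    return [
        GeneSet(f"DECOY_{i + 1:02d}", set(rng.choice(pool, size=size, replace=False)),
                "random decoy set")
        for i in range(n_sets)
    ]


def _cohort_stage(cohort: SyntheticCohort, cfg: PipelineConfig, genesets: list[GeneSet],
                  gsea_seed: int) -> tuple[dict, list]:
    calls = _classify_cohort(cohort, cohort.signatures, cfg.k, cfg.secondary_threshold)
    precision, recall = _precision_recall(calls.consensus_high, cohort.truth_high_set)
    labels = PhenotypeLabels(
        list(cohort.expression.sample_ids),
        ["myc_high" if s in calls.consensus_high else "myc_low"
         for s in cohort.expression.sample_ids],
        ("myc_high", "myc_low"),
    )
    enr = gsea(
        cohort.expression, labels, genesets,
        n_perm=cfg.n_perm, seed=gsea_seed, weight_p=cfg.weight_p, perm_type=cfg.perm_type,
    )
    summary = {
        "n_samples": cohort.expression.n_samples,
        "consensus_high": sorted(calls.consensus_high),
        "per_signature_counts": {k: len(v) for k, v in calls.per_signature_high.items()},
        "venn_counts": {"+".join(sorted(k)): v for k, v in calls.venn_counts.items()},
        "consensus_precision": precision,
        "consensus_recall": recall,
        "enrichment": [
            {
                "set": r.set_name, "size": r.size, "es": r.es, "nes": r.nes,
                "p_nominal": r.p_nominal, "fdr_q": r.fdr_q, "perm_type": r.perm_type,
            }
            for r in enr
        ],
    }
    return summary, enr


def run_full_analysis(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Run the complete synthetic analysis and return the JSON-ready report.

    With ``out_dir`` the intermediate artifacts (expression TSVs, GMT, CLS,
    screen table, truth sidecars) and ``report.json`` are written as well.
    """
    t0 = time.perf_counter()
    seeds = _child_seeds(config.seed, 8)
    cohort_a = simulate_cohort(dataclasses.replace(config.cohort_a, seed=seeds[0]))
    cohort_b = simulate_cohort(dataclasses.replace(config.cohort_b, seed=seeds[1]))
    _stage("simulate", t0, n_a=cohort_a.expression.n_samples, n_b=cohort_b.expression.n_samples)

    planted_union = set().union(
        *(s.genes for s in cohort_a.signatures + cohort_b.signatures)
    )
    decoys = _decoy_sets(cohort_a.expression.gene_ids, config.n_decoy_sets,
                         config.decoy_size, seeds[2], exclude=planted_union)

    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "provenance": {
            "package_version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "config_sha256": hashlib.sha256(
                json.dumps(config.to_dict(), sort_keys=True).encode()
            ).hexdigest(),
        },
    }

    results_by_cohort = {}
    for name, cohort, gsea_seed in (("cohort_a", cohort_a, seeds[3]),
                                    ("cohort_b", cohort_b, seeds[4])):
        genesets = cohort.signatures + decoys
        summary, enr = _cohort_stage(cohort, config, genesets, gsea_seed)
        report[name] = summary
        results_by_cohort[name] = enr
        _stage(f"classify+gsea[{name}]", t0, n_sets=len(genesets))

    shared, venn = intersect_enriched(
        results_by_cohort["cohort_a"], results_by_cohort["cohort_b"], config.q_threshold
    )
    report["signature_intersection"] = {
        "q_threshold": config.q_threshold,
        "shared": sorted(shared),
        "venn": venn,
    }

    # single-dose screen on a 4-line panel (2 MYC-high, 2 MYC-low)
    screen_lines = {"line_hi1": True, "line_hi2": True, "line_lo1": False, "line_lo2": False}
    table, planted_hits = simulate_screen(
        dataclasses.replace(config.screen, seed=seeds[5]), screen_lines
    )
    groups = PhenotypeLabels(
        list(screen_lines),
        ["myc_high" if v else "myc_low" for v in screen_lines.values()],
        ("myc_high", "myc_low"),
    )
    screen_results = score_single_dose_screen(table, groups)
    called_hits = {r.drug_id for r in screen_results if r.is_hit}
    report["screen"] = {
        "n_drugs": len(table.drug_ids),
        "hits": sorted(called_hits),
        "n_hits": len(called_hits),
        "planted_hits": sorted(planted_hits),
        "hits_match_planted": called_hits == planted_hits,
        "top_ranked": [
            {"drug": r.drug_id, "ratio": r.ratio, "is_hit": r.is_hit}
            for r in screen_results[:15]
        ],
    }
    _stage("screen", t0, n_drugs=len(table.drug_ids))

    # cell-line panel: dose-response fits -> sensitive-quartile phenotype -> GSEA
    panel = simulate_cohort(dataclasses.replace(config.line_panel, seed=seeds[6]))
    doses = np.array([1.0, 3.16, 10.0, 31.6, 100.0, 316.0, 1000.0])  # 7-point dilution, nM
    rng = np.random.default_rng(seeds[7])
    gi50_map: dict[str, float] = {}
    for line in panel.expression.sample_ids:
        true_gi50 = 30.0 if panel.truth_high[line] else 300.0  # left-shifted when MYC-high
        viab = simulate_dose_response(
            (0.0, 100.0, true_gi50, 1.2), doses, noise_cv=0.05,
            seed=int(rng.integers(2**31)),
        )
        gi50_map[line] = fit_4pl(doses, viab, drug_id="bortezomib", cell_line_id=line).gi50
    pheno = quartile_stratify(gi50_map, lower_is_sensitive=True,
                              metric_name="bortezomib_gi50", quantile=config.quartile)
    panel_sets = panel.signatures + _decoy_sets(
        panel.expression.gene_ids, config.n_decoy_sets, config.decoy_size, seeds[2],
        exclude=set().union(*(s.genes for s in panel.signatures)),
    )
    quartile_enr = gsea(
        panel.expression, pheno.to_labels(), panel_sets,
        n_perm=config.n_perm, seed=seeds[7], weight_p=config.weight_p,
        perm_type=config.perm_type,
    )
    report["quartile_phenotype"] = {
        "metric": pheno.metric_name,
        "boundary": pheno.quartile_boundary,
        "sensitive_lines": sorted(pheno.sensitive_set),
        "enrichment": [
            {"set": r.set_name, "es": r.es, "nes": r.nes, "p_nominal": r.p_nominal,
             "fdr_q": r.fdr_q}
            for r in quartile_enr
        ],
    }
    _stage("quartile", t0, n_lines=panel.expression.n_samples)

    # survival + subtype association on cohort A consensus calls
    records = [
        SurvivalRecord(s, cohort_a.survival_time[s], cohort_a.survival_event[s],
                       "myc_high" if s in report["cohort_a"]["consensus_high"] else "myc_low")
        for s in cohort_a.expression.sample_ids
    ]
    chi2, logrank_p = logrank_test(records)
    high = set(report["cohort_a"]["consensus_high"])
    a = sum(1 for s in high if cohort_a.subtype[s] == "squamous")
    b = len(high) - a
    rest = [s for s in cohort_a.expression.sample_ids if s not in high]
    c = sum(1 for s in rest if cohort_a.subtype[s] == "squamous")
    d = len(rest) - c
    report["survival"] = {"logrank_chi2": chi2, "logrank_p": logrank_p}
    report["subtype_association"] = {
        "table": [[a, b], [c, d]],
        "fisher_p": fisher_exact(ContingencyTable2x2(a, b, c, d)),
    }
    _stage("stats", t0)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_expression_matrix(cohort_a.expression, out / "cohort_a.tsv")
        write_expression_matrix(cohort_b.expression, out / "cohort_b.tsv")
        write_gmt(cohort_a.signatures + decoys, out / "genesets.gmt")
        write_drug_table(table, out / "screen.tsv")
        write_phenotype(groups, out / "screen_groups.cls")
        truth_lines = [f"{s}\t{int(cohort_a.truth_high[s])}" for s in cohort_a.expression.sample_ids]
        (out / "cohort_a_truth.tsv").write_text("\n".join(truth_lines) + "\n", encoding="utf-8")
        (out / "report.json").write_text(serialize_report(report), encoding="utf-8")
    return report


def serialize_report(report: dict) -> str:
    """Canonical JSON serialization (sorted keys) so equal runs are byte-equal."""
    return json.dumps(report, sort_keys=True, indent=2) + "\n"
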