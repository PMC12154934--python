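"""End-to-end orchestration: simulate -> attribute -> aggregate -> evaluate.

One :class:`RunConfig` describes a corpus (synthetic or user records), a
grid of (model id, embedder, predictor) triples, a method list and the
modes to run.  ``run_pipeline`` produces, per protein and grid cell, the
residue-impact matrix (XE for embedding mode, XP for prediction mode),
then the full property-test result set, pass-count summaries, distance
profiles and (optionally) infidelity records.  A failure in one grid cell
is recorded and never corrupts the others.

``reproduce_reference_tables`` recomputes every summary aggregate from the
packaged reference p-value fixture alone and diffs it against the expected
values shipped with the package.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import aggregate, stats
from .attribution import (
    AttributionConfig,
    compute_embedding_attribution,
    compute_prediction_attribution,
)
from .data import (
    MODES,
    XAI_METHODS,
    ProteinRecord,
    generate_synthetic_proteins,
    load_property_table,
    load_reported_pvalues,
)
from .infidelity import PerturbationSpec, embedding_infidelity, prediction_infidelity
from .models import ToyEmbedderModel, WindowPredictor, as_handle


@dataclass
class RunConfig:
    """Everything one reproducible analysis run needs."""

    models: list[tuple[str, ToyEmbedderModel, WindowPredictor]]
    methods: tuple[str, ...] = XAI_METHODS
    modes: tuple[str, ...] = MODES
    proteins: list[ProteinRecord] | None = None
    n_proteins: int = 20
    length_range: tuple[int, int] = (30, 44)
    interaction_rate: float = 0.3
    w: int = 4
    alpha: float = 0.05
    transform: str = "signed"
    seed: int = 0
    attribution: AttributionConfig | None = None
    compute_infidelity: bool = False
    perturbation: PerturbationSpec | None = None
    out_dir: str | Path | None = None

    def corpus(self) -> list[ProteinRecord]:
        if self.proteins is not None:
            return self.proteins
        return generate_synthetic_proteins(
            self.n_proteins, self.length_range, self.interaction_rate, self.seed
        )


@dataclass
class PipelineResult:
    matrices: dict  # (model_id, method, mode) -> list of (record, ndarray)
    results: list
    summary: stats.PassCountSummary
    distance_profiles: dict
    infidelity: dict = field(default_factory=dict)
    failures: list = field(default_factory=list)
    manifest: dict = field(default_factory=dict)


def _method_handles(embedder, predictor, method):
    rule = {"deconvolution": "deconvolution", "guided_backprop": "guided"}.get(
        method, "true_gradient"
    )
    return as_handle(embedder, rule), as_handle(predictor, rule)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full grid; per-cell failures are recorded, not fatal."""
    corpus = config.corpus()
    min_n = min(r.length for r in corpus)
    if 2 * config.w + 1 > min_n:
        raise ValueError(
            f"window 2w+1={2 * config.w + 1} exceeds shortest sequence ({min_n})"
        )
    base_cfg = config.attribution or AttributionConfig()
    matrices: dict = {}
    infid: dict = {}
    failures: list = []
    for model_id, embedder, predictor in config.models:
        for method in config.methods:
            h_emb, h_pred = _method_handles(embedder, predictor, method)
            cfg = dataclasses.replace(base_cfg, method=method, seed=config.seed)
            for rec in corpus:
                x = embedder.embed(rec.sequence)
                try:
                    streamed = compute_embedding_attribution(h_emb, x, cfg, stream=True)
                    if "embedding" in config.modes:
                        XE = aggregate.xe_from_T(
                            streamed.T,
                            {"model": model_id, "method": method, "protein": rec.name},
                        )
                        matrices.setdefault((model_id, method, "embedding"), []).append(
                            (rec, XE.X)
                        )
                    if "prediction" in config.modes:
                        emb_out = embedder.forward(x)
                        P = compute_prediction_attribution(h_pred, emb_out, config.w, cfg)
                        XP = aggregate.compose_XP(
                            P, streamed.T, config.w,
                            provenance={"model": model_id, "method": method,
                                        "protein": rec.name},
                        )
                        matrices.setdefault((model_id, method, "prediction"), []).append(
                            (rec, XP.X)
                        )
                    if config.compute_infidelity:
                        _cell_infidelity(
                            config, infid, model_id, method, rec, embedder,
                            predictor, h_emb, h_pred, x, cfg
                        )
                except Exception as exc:  # per-cell isolation
                    failures.append(
                        {"model": model_id, "method": method, "protein": rec.name,
                         "error": f"{type(exc).__name__}: {exc}"}
                    )

    prop_table = load_property_table()
    results = stats.run_property_tests(matrices, prop_table, transform=config.transform)
    summary = stats.summarize_pass_counts(results, alpha=config.alpha)
    profiles = {
        key: stats.distance_profile([m for _, m in pairs])
        for key, pairs in matrices.items()
    }
    manifest = {
        "seed": config.seed,
        "n_proteins": len(corpus),
        "models": [m[0] for m in config.models],
        "methods": list(config.methods),
        "modes": list(config.modes),
        "w": config.w,
        "alpha": config.alpha,
        "transform": config.transform,
        "n_matrices_per_protein": len(config.models) * len(config.methods) * len(config.modes),
        "n_failures": len(failures),
    }
    result = PipelineResult(matrices, results, summary, profiles, infid, failures, manifest)
    if config.out_dir is not None:
        _write_outputs(result, config)
    return result


def _cell_infidelity(config, infid, model_id, method, rec, embedder, predictor,
                     h_emb, h_pred, x, cfg):
    spec = config.perturbation or PerturbationSpec(seed=config.seed)
    E = compute_embedding_attribution(h_emb, x, cfg, stream=False)
    I_E, _ = embedding_infidelity(h_emb, x, E, spec)
    emb_out = embedder.forward(x)
    P = compute_prediction_attribution(h_pred, emb_out, config.w, cfg)
    record = prediction_infidelity(h_pred, emb_out, P, I_E, config.w, spec)
    infid.setdefault((model_id, method), []).append((rec.name, record))


def _write_outputs(result: PipelineResult, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame = stats.results_frame(result.results)
    frame.to_csv(out / "property_tests.tsv", sep="\t", index=False)
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=1, sort_keys=True)
    summary = {
        "grand_total": result.summary.grand_total,
        "categorical_total": result.summary.categorical_total,
        "numerical_total": result.summary.numerical_total,
        "failures": result.failures,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    mdir = out / "matrices"
    mdir.mkdir(exist_ok=True)
    for (model_id, method, mode), pairs in result.matrices.items():
        for rec, X in pairs:
            path = mdir / f"{model_id}_{method}_{mode}_{rec.name}.tsv"
            aggregate.write_impact_tsv(
                aggregate.ResidueImpactMatrix(X, mode), rec.sequence, path
            )


# ---------------------------------------------------------------------------
# reference-table reproduction
# ---------------------------------------------------------------------------

def _expected_summary() -> dict:
    path = Path(importlib.resources.files("protattr") / "data" / "reference_summary.json")
    with open(path) as fh:
        return json.load(fh)


def reproduce_reference_tables(alpha: float = 0.05) -> dict:
    """Recompute every summary aggregate from the packaged p-value fixture.

    Returns {"computed": ..., "expected": ..., "mismatches": [...]}; the
    expected values only apply at alpha = 0.05 (other thresholds return the
    recomputation with no diff).
    """
    fixture = load_reported_pvalues()
    summary = stats.summarize_pass_counts(fixture, alpha=alpha)
    cross = stats.crosstab_embedding_vs_prediction(fixture, alpha=alpha)
    excl = stats.exclusive_pass_analysis(fixture, alpha=alpha)

    computed = {
        "grand_total": summary.grand_total,
        "categorical_total": summary.categorical_total,
        "numerical_total": summary.numerical_total,
        "categorical_pct": summary.categorical_pct,
        "numerical_pct": summary.numerical_pct,
        "by_method_total": {
            m: [int(summary.by_method_model.loc[m, (mod, k)]) for mod, k in
                [("all", "categorical"), ("all", "numerical"), ("all", "total")]]
            for m in summary.by_method_model.index
        },
        "by_model_total": {
            mod: [int(summary.by_method_model[(mod, k)].sum())
                  for k in ("categorical", "numerical", "total")]
            for mod in ("ProtBERT", "ProtT5", "Ankh")
        },
        "by_method_testtype": {
            m: [int(v) for v in summary.by_method_testtype.loc[m]]
            for m in summary.by_method_testtype.index
        },
        "by_model_testtype": {
            tt: {mod: [int(summary.by_model_testtype.loc[tt, (mod, "categorical")]),
                       int(summary.by_model_testtype.loc[tt, (mod, "numerical")])]
                 for mod in ("ProtBERT", "ProtT5", "Ankh", "all")}
            for tt in stats.TEST_TYPES
        },
        "crosstab_overall": {c: int(cross.loc[c, ("all", "total")])
                             for c in ("pass|pass", "pass|fail", "fail|pass",
                                       "fail|fail", "total")},
        "crosstab_per_model": {
            mod: {kind: [int(cross.loc[c, (mod, kind)])
                         for c in ("pass|pass", "pass|fail", "fail|pass", "fail|fail")]
                  for kind in ("categorical", "numerical")}
            for mod in ("ProtBERT", "ProtT5", "Ankh")
        },
        "exclusivity": {
            kind: {"exactly_one": s.exactly_one, "at_least_one": s.at_least_one,
                   "only_counts": s.only_counts,
                   "pct_of_passed": s.pct_of_passed, "pct_of_grid": s.pct_of_grid}
            for kind, s in excl.items()
        },
    }

    mismatches: list[str] = []
    if alpha == 0.05:
        exp = _expected_summary()

        def check(name, got, want):
            if got != want:
                mismatches.append(f"{name}: computed {got} != expected {want}")

        for key in ("grand_total", "categorical_total", "numerical_total",
                    "categorical_pct", "numerical_pct"):
            check(key, computed[key], exp[key])
        for m, want in exp["by_method_total"].items():
            check(f"method {m}", computed["by_method_total"][m], want)
        for mod, want in exp["by_model_total"].items():
            check(f"model {mod}", computed["by_model_total"][mod], want)
        for m, want in exp["by_method_testtype"].items():
            check(f"testtype {m}", computed["by_method_testtype"][m], want)
        for tt, row in exp["by_model_testtype"].items():
            for mod, want in row.items():
                check(f"testtype {tt}/{mod}", computed["by_model_testtype"][tt][mod], want)
        for c, want in exp["crosstab_overall"].items():
            check(f"crosstab {c}", computed["crosstab_overall"][c], want)
        for mod, kinds in exp["crosstab_per_model"].items():
            for kind, want in kinds.items():
                check(f"crosstab {mod}/{kind}", computed["crosstab_per_model"][mod][kind], want)
        e = exp["exclusivity"]
        c = computed["exclusivity"]
        check("exclusivity cat exactly_one", c["categorical"]["exactly_one"],
              e["categorical"]["exactly_one"])
        check("exclusivity cat only_Ankh", c["categorical"]["only_counts"]["Ankh"],
              e["categorical"]["only_Ankh"])
        check("exclusivity cat pct_of_grid", c["categorical"]["pct_of_grid"],
              e["categorical"]["pct_of_grid"])
        check("exclusivity num only_ProtT5", c["numerical"]["only_counts"]["ProtT5"],
              e["numerical"]["only_ProtT5"])
        check("exclusivity num pct_of_passed", c["numerical"]["pct_of_passed"],
              e["numerical"]["pct_of_passed"])
        check("exclusivity all pct_of_passed", c["all"]["pct_of_passed"],
              e["all"]["pct_of_passed"])
        return {"computed": computed, "expected": exp, "mismatches": mismatches}
    return {"computed": computed, "expected": None, "mismatches": mismatches}
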