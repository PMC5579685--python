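"""End-to-end orchestration: simulate -> classify -> usual intake ->
traits -> correlations -> familiality, with every intermediate written as
CSV and a JSON report of the headline results.

No stage applies a multiple-testing adjustment; reported p-values are
per-comparison and should be read with that caution.
"""
from __future__ import annotations

import json
import sys
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import AnalysisConfig, PipelineConfig, SimulationConfig, dump_config
from .correlations import (
    MAIN_TYPE_SUBTYPES,
    compare_dependent_nonoverlapping,
    compare_independent,
    correlation_table,
    homogeneity_test,
    CorrelationEstimate,
    pair_values,
)
from .foods import person_day_table
from .intake import estimate_usual_intakes, filter_recalls, goldberg_classify
from .pedigree import build_families, tabulate_family_types
from .simulate import TRAIT_VARIABLES, generate_dataset, write_dataset
from .traits import prepare_traits
from .varcomp import fit_variance_components, stratified_familiality, VarCompError

VARIABLES = TRAIT_VARIABLES

_YOUNGER_GROUPS = ("mothers", "fathers", "younger_daughters", "younger_sons")
_OLDER_GROUPS = ("mothers", "fathers", "older_daughters", "older_sons")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _load_inputs(input_dir: str) -> dict[str, pd.DataFrame]:
    base = Path(input_dir)
    data = {}
    for name in ("persons", "recalls", "ffq", "composition"):
        path = base / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing input table: {path}")
        data[name] = pd.read_csv(path)
    return data


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; writes CSVs under config.out_dir and returns the
    report dict (also written as report.json)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ana = config.analysis
    report: dict = {
        "version": __version__,
        "seeds": {"simulation": config.simulation.seed, "analysis": ana.seed},
        "note": "p-values are unadjusted for multiple testing",
    }

    # -- stage: inputs -----------------------------------------------------
    try:
        if config.simulate:
            data = generate_dataset(config.simulation)
            write_dataset(data, out, config.simulation)
        else:
            data = _load_inputs(config.input_dir or config.out_dir)
    except Exception as exc:  # noqa: BLE001 - abort with stage name
        raise StageError("inputs", exc) from exc
    persons, recalls = data["persons"], data["recalls"]
    ffq, composition = data["ffq"], data["composition"]

    # -- stage: pedigree ---------------------------------------------------
    try:
        families, exclusion_log = build_families(persons, seed=ana.seed)
        table, summary = tabulate_family_types(families)
        table.to_csv(out / "family_types.csv", index=False)
        report["family_summary"] = summary
        report["pedigree_exclusions"] = exclusion_log
    except Exception as exc:
        raise StageError("pedigree", exc) from exc

    # -- stage: classify ---------------------------------------------------
    try:
        person_days = person_day_table(recalls, composition)
        # recall-level completeness/imputation screen
        flags = recalls.groupby(["person_id", "day_index"]).agg(
            complete=("complete", "all")
        ).reset_index() if "complete" in recalls.columns else person_days[
            ["person_id", "day_index"]
        ].assign(complete=True)
        flags["n_imputed"] = recalls.groupby(["person_id", "day_index"])[
            "imputed"
        ].sum().to_numpy() if "imputed" in recalls.columns else 0
        kept, recall_log = filter_recalls(flags, ana.max_imputed)
        person_days = person_days.merge(
            kept[["person_id", "day_index"]], on=["person_id", "day_index"]
        )
        person_days.to_csv(out / "person_days.csv", index=False)
        report["recall_exclusions"] = recall_log
    except Exception as exc:
        raise StageError("classify", exc) from exc

    # -- stage: usual intake ----------------------------------------------
    try:
        info = persons.set_index("person_id")
        gold = [
            goldberg_classify(
                e, info.loc[p, "sex"], int(info.loc[p, "age"]), ana.goldberg
            )
            for p, e in zip(person_days["person_id"], person_days["energy_kcal"])
        ]
        gold = pd.Series(gold, index=person_days.index, name="goldberg")
        exclusions = person_days[["person_id", "day_index"]].assign(status=gold)
        exclusions[exclusions["status"] != "plausible"].to_csv(
            out / "exclusions.csv", index=False
        )
        report["goldberg"] = gold.value_counts().to_dict()
        usual, models = estimate_usual_intakes(
            person_days, persons, ffq, VARIABLES, config=ana
        )
        usual.to_csv(out / "usual_intake.csv", index=False)
        params = {
            key: {
                "lambda": m.lam,
                "beta": dict(zip(m.beta_names, m.beta)),
                "sigma2_u": m.sigma2_u,
                "sigma2_eps": m.sigma2_eps,
                "loglik": m.loglik,
                "identifiable": m.identifiable,
            }
            for key, m in models.items()
        }
        (out / "usual_intake_models.json").write_text(
            json.dumps(params, indent=2, default=float)
        )
    except Exception as exc:
        raise StageError("usual_intake", exc) from exc

    # -- stage: traits -----------------------------------------------------
    try:
        traits, logs = prepare_traits(usual, persons, config=ana)
        traits_split, logs_split = prepare_traits(
            usual, persons, config=ana, age_split=True
        )
        traits.to_csv(out / "traits.csv", index=False)
        traits_split.to_csv(out / "traits_age_split.csv", index=False)
        (out / "trait_preparation.json").write_text(
            json.dumps([asdict(l) for l in logs + logs_split], indent=2)
        )
    except Exception as exc:
        raise StageError("traits", exc) from exc

    # -- stage: correlations ------------------------------------------------
    try:
        corr_frames, test_rows = [], []
        for variable in VARIABLES:
            corr_frames.append(correlation_table(families, traits, variable))
            # homogeneity among subtypes within each main type
            sub_tab = corr_frames[-1]
            for main, subtypes in MAIN_TYPE_SUBTYPES.items():
                ests = [
                    CorrelationEstimate(
                        row["subtype"], row["r"], row["se"], row["n_pairs"], row["method"]
                    )
                    for _, row in sub_tab.iterrows()
                    if row["subtype"] in subtypes and row["n_pairs"] > 3
                ]
                if len(ests) >= 2:
                    res = homogeneity_test(ests)
                    test_rows.append(
                        {
                            "variable": variable,
                            "contrast": f"homogeneity:{main}",
                            "statistic": res.statistic,
                            "df": res.df,
                            "p": round(res.p, 3),
                        }
                    )
            # younger vs older contrasts from the age-split traits
            young = traits_split[traits_split["group"].isin(_YOUNGER_GROUPS)]
            old = traits_split[traits_split["group"].isin(_OLDER_GROUPS)]
            for main in ("parent_offspring", "sibling"):
                pair_sets = []
                for sub_traits in (young, old):
                    pairs = pair_values(families, sub_traits, variable)
                    arrs = [
                        pairs[s]
                        for s in MAIN_TYPE_SUBTYPES[main]
                        if s in pairs and len(pairs[s])
                    ]
                    pair_sets.append(
                        np.concatenate(arrs, axis=0) if arrs else np.empty((0, 2))
                    )
                if all(len(a) > 3 for a in pair_sets):
                    from .correlations import interclass_correlation, intraclass_correlation

                    est = (
                        intraclass_correlation
                        if main == "sibling"
                        else interclass_correlation
                    )
                    e_y, e_o = est(pair_sets[0]), est(pair_sets[1])
                    res = compare_independent(e_y.r, e_y.n_pairs, e_o.r, e_o.n_pairs)
                    test_rows.append(
                        {
                            "variable": variable,
                            "contrast": f"younger_vs_older:{main}",
                            "statistic": res.statistic,
                            "df": None,
                            "p": round(res.p, 3),
                        }
                    )
        correlations = pd.concat(corr_frames, ignore_index=True)
        correlations.to_csv(out / "correlations.csv", index=False)
        report["correlations"] = {
            v: {
                f"{row['main_type']}/{row['subtype']}": round(row["r"], 3)
                for _, row in correlation_table(families, traits, v).iterrows()
                if row["subtype"] == "all"
            }
            for v in VARIABLES
        }
        # healthy vs unhealthy, dependent comparison on parent-offspring pairs
        from .correlations import paired_pair_values

        h_arr, u_arr = paired_pair_values(
            families, traits, "healthy_sum", "unhealthy_sum",
            MAIN_TYPE_SUBTYPES["parent_offspring"],
        )
        if len(h_arr) > 3:
            mat = np.corrcoef(
                np.column_stack([h_arr[:, 0], h_arr[:, 1], u_arr[:, 0], u_arr[:, 1]]).T
            )
            res = compare_dependent_nonoverlapping(mat, len(h_arr))
            test_rows.append(
                {
                    "variable": "healthy_vs_unhealthy",
                    "contrast": "parent_offspring:dependent",
                    "statistic": res.statistic,
                    "df": None,
                    "p": round(res.p, 3),
                }
            )
            report["healthy_vs_unhealthy_parent_offspring_p"] = round(res.p, 3)
        pd.DataFrame(test_rows).to_csv(out / "tests.csv", index=False)
    except Exception as exc:
        raise StageError("correlations", exc) from exc

    # -- stage: familiality --------------------------------------------------
    try:
        fam_rows = []
        report["familiality"] = {}
        for variable in VARIABLES:
            tv = traits[traits["variable"] == variable].set_index("person_id")["value"]
            fit = fit_variance_components(families, tv, ci_method=ana.ci_method)
            fam_rows.append(_fit_row(variable, "all", fit))
            report["familiality"][variable] = {
                "F": round(fit.familiality, 3),
                "ci": [round(x, 3) for x in fit.ci],
            }
            tv_split = traits_split[traits_split["variable"] == variable].set_index(
                "person_id"
            )["value"]
            try:
                strat = stratified_familiality(
                    families, tv_split, cutoff_years=ana.age_cutoff
                )
                fam_rows.append(_fit_row(variable, "younger", strat["younger"]))
                fam_rows.append(_fit_row(variable, "older", strat["older"]))
            except VarCompError:
                pass
        pd.DataFrame(fam_rows).to_csv(out / "familiality.csv", index=False)
    except Exception as exc:
        raise StageError("familiality", exc) from exc

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True,
                                                default=float))
    dump_config(config, out / "pipeline_config.yaml")
    return report


def _fit_row(variable: str, stratum: str, fit) -> dict:
    return {
        "variable": variable,
        "stratum": stratum,
        "sigma2_g": fit.sigma2_g,
        "sigma2_c": fit.sigma2_c,
        "sigma2_e": fit.sigma2_e,
        "familiality": fit.familiality,
        "ci_lo": fit.ci[0] if fit.ci else np.nan,
        "ci_hi": fit.ci[1] if fit.ci else np.nan,
        "loglik": fit.loglik,
        "model": fit.model,
        "flags": ";".join(fit.boundary + (["ridge"] if fit.ridge else [])),
    }


def main(argv: list[str] | None = None) -> int:  # pragma: no cover - thin wrapper
    from .cli import main as cli_main

    return cli_main(argv)


if __name__ == "__main__":  # pragma: no cover
    sys.exit(main())
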