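"""The canonical model sequence over the eight affect ratings.

Encodes the measurement-model ladder (single factor, four correlated
factors, a hierarchical variant, and the four-factor model with three
freed parameters), its covariate extensions (age, cognition, demographics)
and the brain-behavior models over gray-matter source loadings, together
with the comparison protocol: the single-vs-four-factor test, the
age-path equality test, the equality-constrained brain model, and the
per-source path-zeroing tests.

Factor naming follows the final interpretation of the four factors:
``PosReactivity`` (positivity from neutral and positive content),
``PosRegulation`` (positivity extracted from negative content),
``NegReactivity`` (negative affect to negative content) and
``BasalNegAffect`` (negative affect to neutral and positive content).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import FACTORS, GM_COLUMNS
from .errt import RATING_COLUMNS
from .sem import (
    FitResult,
    ModelSpec,
    Parameter,
    fit_ml,
    format_p,
    scaled_chi2_diff,
)
from .sem.spec import REGRESSION

__all__ = [
    "LadderReport",
    "build_measurement_models",
    "extend_with_covariates",
    "build_brain_model",
    "zero_out_source",
    "constrain_source_paths_equal",
    "constrain_age_paths_equal",
    "prepare_ladder_data",
    "run_ladder",
]

COVARIATES = ("age", "fluid_iq", "education", "gender", "depression")

_SINGLE_FACTOR = "Emotionality =~ " + " + ".join(RATING_COLUMNS)

_FOUR_FACTOR = """
PosReactivity =~ neutral_pos + poswatch_pos
PosRegulation =~ negreg_pos + negwatch_pos
NegReactivity =~ negreg_neg + negwatch_neg
BasalNegAffect =~ neutral_neg + poswatch_neg + negwatch_neg
"""

_MODIFICATIONS = """
BasalNegAffect =~ poswatch_pos
poswatch_pos ~~ poswatch_neg
negreg_neg ~~ negwatch_pos
"""

_HIERARCHICAL = _FOUR_FACTOR + "\nGeneral =~ " + " + ".join(FACTORS)


def build_measurement_models() -> dict[str, ModelSpec]:
    """The measurement-model ladder.

    ``four_factor`` is the canonical nine-loading structure (df 13);
    ``four_factor_df12`` frees one additional residual covariance to match
    df-12 tabulations of this model family, kept as a documented variant.  ``four_factor_modified`` adds the three freed
    parameters: the positive-watch residual covariance, the cross-loading
    of the positive-watch positive rating on basal negative affect, and
    the regulate-negative/watch-positive residual covariance.
    """
    four = ModelSpec.from_text(_FOUR_FACTOR)
    return {
        "single_factor": ModelSpec.from_text(_SINGLE_FACTOR),
        "four_factor": four,
        "four_factor_df12": ModelSpec.from_text(
            _FOUR_FACTOR + "\nneutral_pos ~~ neutral_neg\n"
        ),
        "hierarchical": ModelSpec.from_text(_HIERARCHICAL),
        "four_factor_modified": ModelSpec.from_text(_FOUR_FACTOR + _MODIFICATIONS),
    }


def extend_with_covariates(spec: ModelSpec, covariates: Sequence[str]) -> ModelSpec:
    """Regress every factor on each covariate (age as a common cause).

    When age is present together with fluid intelligence and/or education,
    the age -> fluid_iq and age -> education paths are added as well.
    """
    unknown = [c for c in covariates if c not in COVARIATES]
    if unknown:
        raise ValueError(f"unknown covariates: {unknown}")
    extra: list[Parameter] = []
    for cov in covariates:
        for f in FACTORS:
            if f not in spec.latent_factors:
                raise ValueError(f"spec lacks factor {f}")
            extra.append(Parameter(REGRESSION, f, cov))
    if "age" in covariates:
        for downstream in ("fluid_iq", "education"):
            if downstream in covariates:
                extra.append(Parameter(REGRESSION, downstream, "age"))
    return spec.with_parameters(extra) if extra else spec


def build_brain_model(
    spec: ModelSpec,
    sources: Sequence[str] = GM_COLUMNS,
    include_age: bool = False,
    n_sources: int = 12,
) -> ModelSpec:
    """Add gray-matter source loadings as putative causes of all factors.

    Education, gender and depression are retained as factor predictors;
    fluid intelligence is excluded (the sources stand in for neural indices
    of cognitive control).  ``include_age`` adds age -> factor paths (age
    then covaries freely with the sources as a fellow exogenous variable).
    """
    sources = list(sources)
    if len(sources) != n_sources:
        raise ValueError(f"expected {n_sources} sources, got {len(sources)}")
    extra: list[Parameter] = []
    predictors = sources + ["education", "gender", "depression"]
    if include_age:
        predictors.append("age")
    for pred in predictors:
        for f in FACTORS:
            extra.append(Parameter(REGRESSION, f, pred))
    return spec.with_parameters(extra)


def zero_out_source(spec: ModelSpec, source: str) -> ModelSpec:
    """Fix the four factor paths of one source to zero (delta-df 4)."""
    return spec.fix_parameters([(REGRESSION, f, source) for f in FACTORS], value=0.0)


def constrain_source_paths_equal(spec: ModelSpec, sources: Sequence[str]) -> ModelSpec:
    """One shared coefficient for every brain-behavior path."""
    keys = [(REGRESSION, f, s) for s in sources for f in FACTORS]
    return spec.label_parameters(keys, label="b_gm_eq")


def constrain_age_paths_equal(spec: ModelSpec) -> ModelSpec:
    """Equality-constrain the four age -> factor paths (delta-df 3)."""
    return spec.label_parameters([(REGRESSION, f, "age") for f in FACTORS], label="b_age_eq")


# --------------------------------------------------------------------------
# report
# --------------------------------------------------------------------------

_ROW_FIELDS = ("model", "chi2_sb", "df", "rmsea", "cfi", "sb", "aic", "converged")


@dataclass
class LadderReport:
    """Fit rows (table style) plus nested-comparison records."""

    rows: list[dict] = field(default_factory=list)
    comparisons: list[dict] = field(default_factory=list)

    def add_fit(self, name: str, fit: FitResult | None) -> None:
        if fit is None or fit.converged == "dnc":
            self.rows.append({"model": name, **{k: None for k in _ROW_FIELDS[1:-1]}, "converged": "dnc"})
            return
        self.rows.append(
            {
                "model": name,
                "chi2_sb": round(fit.chi2_sb if fit.chi2_sb is not None else fit.chi2_ml, 2),
                "df": fit.df,
                "rmsea": round(fit.rmsea, 3),
                "cfi": round(fit.cfi, 3),
                "sb": round(fit.sb_scaling, 2) if fit.sb_scaling else None,
                "aic": round(fit.aic_, 1),
                "converged": fit.converged,
            }
        )

    def add_comparison(self, restricted: str, full: str, delta: float, ddf: int, p: float) -> None:
        self.comparisons.append(
            {
                "restricted": restricted,
                "full": full,
                "delta_chi2": round(delta, 2),
                "delta_df": ddf,
                "p": p,
                "p_str": format_p(p),
            }
        )

    def to_dict(self) -> dict:
        return {"models": self.rows, "comparisons": self.comparisons}

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_markdown(self) -> str:
        head = "| Model | chi2 (SB) | df | RMSEA | CFI | SB | AIC |\n|---|---|---|---|---|---|---|"
        lines = [head]
        for r in self.rows:
            if r["converged"] == "dnc":
                lines.append(f"| {r['model']} | DNC | DNC | DNC | DNC | DNC | DNC |")
            else:
                lines.append(
                    f"| {r['model']} | {r['chi2_sb']} | {r['df']} | {r['rmsea']} "
                    f"| {r['cfi']} | {r['sb']} | {r['aic']} |"
                )
        if self.comparisons:
            lines.append("")
            lines.append("| Restricted | Full | delta chi2 | delta df | p |\n|---|---|---|---|---|")
            for c in self.comparisons:
                lines.append(
                    f"| {c['restricted']} | {c['full']} | {c['delta_chi2']} "
                    f"| {c['delta_df']} | {c['p_str']} |"
                )
        return "\n".join(lines)


def prepare_ladder_data(data: pd.DataFrame) -> pd.DataFrame:
    """Z-score the continuous covariates and source columns.

    Ratings keep their native scale; age, fluid intelligence, education and
    the gray-matter source loadings are standardized so all fitted models
    are well conditioned and covariate paths read as standardized effects.
    Binary gender/depression stay 0/1.
    """
    out = data.copy()
    cols = [c for c in ("age", "fluid_iq", "education") if c in out.columns]
    cols += [c for c in out.columns if c.startswith("src_")]
    for c in cols:
        sd = out[c].std()
        if sd > 0:
            out[c] = (out[c] - out[c].mean()) / sd
    return out


def _try_fit(spec: ModelSpec, data: pd.DataFrame, **kwargs) -> FitResult | None:
    try:
        fit = fit_ml(spec, data, **kwargs)
    except Exception:  # noqa: BLE001 - a failed row must not abort the ladder
        return None
    return fit


def run_ladder(
    data: pd.DataFrame,
    sources: Sequence[str] | None = None,
    include_brain: bool | None = None,
    **fit_kwargs,
) -> LadderReport:
    """Fit the full model sequence on a cohort table and report it.

    ``data`` must contain the eight rating columns plus whatever covariate
    columns the fitted models need (age, fluid_iq, education, gender,
    depression and, for the brain models, twelve source columns, by
    default ``src_*``).  Rows that fail to converge are recorded as DNC and
    never abort the ladder.
    """
    data = prepare_ladder_data(data)
    specs = build_measurement_models()
    report = LadderReport()
    fits: dict[str, FitResult | None] = {}

    for name in ("single_factor", "four_factor", "hierarchical", "four_factor_modified"):
        fits[name] = _try_fit(specs[name], data, **fit_kwargs)
        report.add_fit(name, fits[name])

    modified = specs["four_factor_modified"]
    with_age = extend_with_covariates(modified, ["age"])
    fits["modified_with_age"] = _try_fit(with_age, data, **fit_kwargs)
    report.add_fit("modified_with_age", fits["modified_with_age"])

    cognition = extend_with_covariates(modified, ["age", "education", "fluid_iq"])
    fits["with_age_edu_iq"] = _try_fit(cognition, data, **fit_kwargs)
    report.add_fit("with_age_edu_iq", fits["with_age_edu_iq"])

    demo = extend_with_covariates(
        modified, ["age", "education", "fluid_iq", "gender", "depression"]
    )
    fits["with_age_edu_iq_gender_dep"] = _try_fit(demo, data, **fit_kwargs)
    report.add_fit("with_age_edu_iq_gender_dep", fits["with_age_edu_iq_gender_dep"])

    # comparisons on the measurement side
    if fits["single_factor"] and fits["four_factor"]:
        try:
            d, ddf, p = scaled_chi2_diff(fits["single_factor"], fits["four_factor"], check="df")
            report.add_comparison("single_factor", "four_factor", d, ddf, p)
        except (ValueError, RuntimeError):
            pass
    if fits["modified_with_age"]:
        eq = constrain_age_paths_equal(with_age)
        fit_eq = _try_fit(eq, data, **fit_kwargs)
        report.add_fit("modified_with_age_equal_paths", fit_eq)
        if fit_eq:
            try:
                d, ddf, p = scaled_chi2_diff(fit_eq, fits["modified_with_age"])
                report.add_comparison("modified_with_age_equal_paths", "modified_with_age", d, ddf, p)
            except (ValueError, RuntimeError):
                pass

    # brain-behavior models
    if sources is None and include_brain is not False:
        sources = [c for c in GM_COLUMNS if c in data.columns]
    if sources and len(sources) == 12:
        brain_spec = build_brain_model(modified, sources)
        fit_brain = _try_fit(brain_spec, data, **fit_kwargs)
        fits["brain"] = fit_brain
        report.add_fit("four_factor_gm_edu", fit_brain)

        eq_spec = constrain_source_paths_equal(brain_spec, sources)
        fit_eq = _try_fit(eq_spec, data, **fit_kwargs)
        report.add_fit("four_factor_gm_edu_equal", fit_eq)
        if fit_brain and fit_eq:
            try:
                d, ddf, p = scaled_chi2_diff(fit_eq, fit_brain)
                report.add_comparison("four_factor_gm_edu_equal", "four_factor_gm_edu", d, ddf, p)
            except (ValueError, RuntimeError):
                pass

        if fit_brain:
            for src in sources:
                fit_zero = _try_fit(zero_out_source(brain_spec, src), data, **fit_kwargs)
                if fit_zero:
                    try:
                        d, ddf, p = scaled_chi2_diff(fit_zero, fit_brain)
                        report.add_comparison(f"zero_{src}", "four_factor_gm_edu", d, ddf, p)
                    except (ValueError, RuntimeError):
                        pass

        age_brain = build_brain_model(modified, sources, include_age=True)
        fit_age_brain = _try_fit(age_brain, data, **fit_kwargs)
        report.add_fit("four_factor_gm_age", fit_age_brain)

    return report
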