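"""Case-control logistic association under multiple genetic models.

Disease status is regressed on a coded genotype plus covariates (gender,
age, smoking, drinking by default) by unconditional maximum-likelihood
logistic regression; the effect is reported as an odds ratio with a Wald
95% CI.  Genetic codings: additive (0/1/2 effect-allele count), recessive
(homozygous effect vs rest), allelic (each subject expanded to two allele
observations), and genotype contrast (homozygote vs homozygote, dropping
heterozygotes).  Stages are combined either by a pooled re-fit with stage
indicators or by fixed-effect inverse-variance meta-analysis of log-ORs.

The modelling surface follows the Model -> fit() -> Results idiom:

>>> res = CaseControlModel(cohort, model="additive").fit()
>>> res.or_, res.ci_low, res.ci_high, res.p
>>> print(res.summary())
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "GENETIC_MODELS",
    "code_genetic_model",
    "CaseControlModel",
    "AssociationResult",
    "SeparationError",
    "combine_stages",
]

GENETIC_MODELS = ("additive", "recessive", "allelic", "genotype_contrast")
_Z95 = 1.959964


class SeparationError(RuntimeError):
    """The logistic MLE diverged (complete/quasi-complete separation)."""


def code_genetic_model(dosage: np.ndarray, model: str):
    """Code dosages for a genetic model.

    Returns ``(design, row_index)`` where ``design`` is the genotype column
    and ``row_index`` maps design rows back to subjects (subjects are
    duplicated under the allelic model and subset under genotype_contrast).
    """
    d = np.asarray(dosage, dtype=float)
    if not np.isin(d, (0, 1, 2)).all():
        raise ValueError("dosage must be in {0, 1, 2}")
    idx = np.arange(d.size)
    if model == "additive":
        return d.copy(), idx
    if model == "recessive":
        return (d == 2).astype(float), idx
    if model == "genotype_contrast":
        keep = np.flatnonzero(d != 1)
        return (d[keep] == 2).astype(float), keep
    if model == "allelic":
        # subject -> two allele observations: 0 -> (0,0), 1 -> (0,1), 2 -> (1,1)
        rows = np.repeat(idx, 2)
        allele = np.zeros(2 * d.size)
        allele[1::2] = (d >= 1).astype(float)
        allele[0::2] = (d == 2).astype(float)
        return allele, rows
    raise ValueError(f"unknown genetic model {model!r}")


@dataclass
class AssociationResult:
    """A fitted single-variant association: OR with Wald 95% CI and p."""

    model: str
    or_: float
    ci_low: float
    ci_high: float
    p: float
    beta: float
    se: float
    n_cases: int
    n_controls: int
    stage: str = ""
    method: str = "logistic"
    params: pd.DataFrame | None = field(default=None, repr=False)

    def summary(self) -> str:
        lines = [
            f"case-control association [{self.model}]"
            + (f" stage={self.stage}" if self.stage else ""),
            "=" * 46,
            f"n cases / controls: {self.n_cases:,} / {self.n_controls:,}",
            f"method:             {self.method}",
            f"OR (95% CI):        {self.or_:.3f} ({self.ci_low:.3f}-{self.ci_high:.3f})",
            f"log-OR (SE):        {self.beta:.4f} ({self.se:.4f})",
            f"P:                  {self.p:.3g}",
        ]
        return "\n".join(lines)


class CaseControlModel:
    """Unconditional multivariable logistic model for one variant.

    Parameters
    ----------
    cohort
        DataFrame with ``phenotype`` (1 = case, 0 = control), ``dosage``
        (hard calls in {0,1,2}), and any covariate columns.
    model
        One of :data:`GENETIC_MODELS`.
    covariates
        Covariate column names (default: the standard gender / age /
        smoking / drinking set, restricted to columns present).
    """

    DEFAULT_COVARIATES = ("gender", "age", "smoking", "drinking")

    def __init__(
        self,
        cohort: pd.DataFrame,
        model: str = "additive",
        covariates: list[str] | None = None,
        stage: str = "",
    ):
        if model not in GENETIC_MODELS:
            raise ValueError(f"unknown genetic model {model!r}")
        if cohort["phenotype"].isna().any():
            raise ValueError("missing phenotypes are not allowed")
        if not set(np.unique(cohort["phenotype"])) <= {0, 1}:
            raise ValueError("phenotype must be coded 0/1")
        self.cohort = cohort.reset_index(drop=True)
        self.model = model
        self.stage = stage
        if covariates is None:
            covariates = [c for c in self.DEFAULT_COVARIATES if c in cohort.columns]
        self.covariates = list(covariates)

    def fit(self) -> AssociationResult:
        geno, rows = code_genetic_model(self.cohort["dosage"].to_numpy(), self.model)
        pheno = self.cohort["phenotype"].to_numpy(dtype=float)[rows]
        if len(set(pheno)) < 2:
            raise ValueError("both phenotype classes must be present")
        X = pd.DataFrame({"genotype": geno})
        for c in self.covariates:
            X[c] = self.cohort[c].to_numpy(dtype=float)[rows]
        X = sm.add_constant(X, prepend=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(pheno, X).fit(disp=0, maxiter=100)
            except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as exc:
                raise SeparationError(
                    "logistic MLE failed to converge (separation); consider an exact "
                    "or penalized alternative"
                ) from exc
        beta = float(res.params["genotype"])
        se = float(res.bse["genotype"])
        if not np.isfinite(beta) or not np.isfinite(se) or abs(beta) > 15 or se > 100:
            raise SeparationError(
                "diverging genotype coefficient (separation); consider an exact or "
                "penalized alternative"
            )
        n_cases = int(self.cohort["phenotype"].sum())
        params = pd.DataFrame({"coef": res.params, "se": res.bse, "p": res.pvalues})
        return AssociationResult(
            model=self.model,
            or_=math.exp(beta),
            ci_low=math.exp(beta - _Z95 * se),
            ci_high=math.exp(beta + _Z95 * se),
            p=float(res.pvalues["genotype"]),
            beta=beta,
            se=se,
            n_cases=n_cases,
            n_controls=len(self.cohort) - n_cases,
            stage=self.stage,
            params=params,
        )


def _ivw_meta(results: list[AssociationResult], model: str) -> AssociationResult:
    betas = np.array([r.beta for r in results])
    ses = np.array([r.se for r in results])
    w = 1.0 / ses**2
    beta = float((w * betas).sum() / w.sum())
    se = float(1.0 / math.sqrt(w.sum()))
    z = beta / se
    p = 2.0 * 0.5 * math.erfc(abs(z) / math.sqrt(2.0))
    return AssociationResult(
        model=model,
        or_=math.exp(beta),
        ci_low=math.exp(beta - _Z95 * se),
        ci_high=math.exp(beta + _Z95 * se),
        p=p,
        beta=beta,
        se=se,
        n_cases=sum(r.n_cases for r in results),
        n_controls=sum(r.n_controls for r in results),
        stage="combined",
        method="ivw_meta",
    )


def combine_stages(
    results: list[AssociationResult] | None = None,
    cohorts: dict[str, pd.DataFrame] | None = None,
    model: str = "additive",
    method: str = "ivw_meta",
    covariates: list[str] | None = None,
) -> AssociationResult:
    """Combine per-stage associations.

    ``method='ivw_meta'`` takes fixed-effect inverse-variance weighted mean
    of the per-stage log-ORs (needs ``results``); ``method='pooled'`` re-fits
    a single logistic model on the concatenated subjects with stage
    indicator covariates (needs ``cohorts``).  All stages must use the same
    genetic model and effect-allele orientation — orientation is the
    caller's contract and is never auto-flipped.
    """
    if method == "ivw_meta":
        if not results or len(results) < 2:
            raise ValueError("ivw_meta needs >= 2 per-stage results")
        if len({r.model for r in results}) != 1:
            raise ValueError("all stages must use the same genetic model")
        return _ivw_meta(results, results[0].model)
    if method == "pooled":
        if not cohorts or len(cohorts) < 2:
            raise ValueError("pooled combination needs >= 2 stage cohorts")
        frames = []
        stage_names = sorted(cohorts)
        for name in stage_names:
            df = cohorts[name].copy()
            df["_stage"] = name
            frames.append(df)
        pooled = pd.concat(frames, ignore_index=True)
        for name in stage_names[1:]:  # first stage is the reference
            pooled[f"stage_{name}"] = (pooled["_stage"] == name).astype(float)
        base = CaseControlModel(pooled, model=model, covariates=covariates, stage="combined")
        base.covariates = base.covariates + [f"stage_{n}" for n in stage_names[1:]]
        res = base.fit()
        res.method = "pooled"
        return res
    raise ValueError(f"unknown combination method {method!r}")
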