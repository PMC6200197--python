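"""Presence–absence species distribution modelling.

Per-cell training data come from a binary presence raster and an aligned
stack of environmental factor rasters. The reference model is a binomial
GLM with a logit link on z-scored factors,

    logit P(present) = β₀ + Σⱼ βⱼ (xⱼ − mⱼ)/sⱼ ,

fitted by IRLS (maximum likelihood; optional L2 ridge for separated data).
Model skill is the training-data AUC — the rank-sum (Mann–Whitney)
probability that a random presence cell scores above a random absence cell
— banded as excellent (≥0.9), good (≥0.8), fair (≥0.7), poor (≥0.6), fail
(<0.6). Candidate models are screened by an AUC gate (default 0.9) and the
best survivor is used for prediction. Factor importance is permutation
AUC-drop: how much discrimination is lost when one factor column is
shuffled.

Other model families (maximum entropy, neural networks, support vector
machines) can participate through the same ``fit(...)``/``predict_table``
contract; only the GLM is provided here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .errors import (
    ContractError,
    ConvergenceError,
    DegenerateTrainingError,
    ParameterError,
    SelectionError,
    SeparationError,
)
from .raster import RasterGrid

__all__ = [
    "FactorStack",
    "TrainingTable",
    "build_training",
    "PresenceAbsenceGLM",
    "SDMResults",
    "auc",
    "accuracy_band",
    "select_model",
]

logger = logging.getLogger(__name__)


class FactorStack:
    """An ordered, aligned collection of named factor rasters."""

    def __init__(self, layers: dict[str, RasterGrid]):
        if not layers:
            raise ParameterError("factor stack cannot be empty")
        names = list(layers)
        ref = layers[names[0]]
        for name in names[1:]:
            ref.require_alignment(layers[name], f"factor '{name}'")
        self.layers = dict(layers)

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def template(self) -> RasterGrid:
        return next(iter(self.layers.values()))

    def __getitem__(self, name: str) -> RasterGrid:
        try:
            return self.layers[name]
        except KeyError:
            raise ContractError(f"factor '{name}' is not in the stack")

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def __len__(self) -> int:
        return len(self.layers)

    def copy(self) -> "FactorStack":
        return FactorStack({k: v.copy() for k, v in self.layers.items()})

    def valid_mask(self) -> np.ndarray:
        """Cells where every layer has data."""
        m = self.template.mask.copy()
        for g in self.layers.values():
            m &= g.mask
        return m


@dataclass
class TrainingTable:
    """Per-cell labels and factor values, with provenance indices."""

    labels: np.ndarray          # 0/1 per retained cell
    factors: pd.DataFrame       # one column per factor
    cell_index: np.ndarray      # flat indices into the source grid
    n_dropped: int = 0          # cells lost to nodata in any layer

    @property
    def n_presence(self) -> int:
        return int(self.labels.sum())

    @property
    def n_absence(self) -> int:
        return int((self.labels == 0).sum())

    @property
    def prevalence(self) -> float:
        return float(self.labels.mean())


def build_training(presence: RasterGrid, stack: FactorStack) -> TrainingTable:
    """One training row per cell valid in the presence raster and every factor.

    Rows with nodata in any factor are dropped and counted. Raises if either
    class is absent.
    """
    presence.require_alignment(stack.template, "presence/factor")
    ok = presence.mask & stack.valid_mask()
    n_dropped = int((presence.mask & ~stack.valid_mask()).sum())
    idx = np.flatnonzero(ok.ravel())
    labels = presence.values.ravel()[idx].astype(int)
    cols = {name: stack[name].values.ravel()[idx] for name in stack.names}
    table = TrainingTable(labels, pd.DataFrame(cols), idx, n_dropped)
    if table.n_presence == 0 or table.n_absence == 0:
        raise DegenerateTrainingError(
            f"training needs both classes (presence={table.n_presence}, "
            f"absence={table.n_absence})"
        )
    return table


def auc(labels, scores) -> float:
    """Rank-sum AUC: (concordant pairs + ½ ties) / (n₁·n₀)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise DegenerateTrainingError("AUC undefined with a single class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def accuracy_band(auc_value: float) -> str:
    """Qualitative AUC band; boundary values join the higher band."""
    if not 0.0 <= auc_value <= 1.0:
        raise ParameterError("AUC must lie in [0, 1]")
    if auc_value >= 0.9:
        return "excellent"
    if auc_value >= 0.8:
        return "good"
    if auc_value >= 0.7:
        return "fair"
    if auc_value >= 0.6:
        return "poor"
    return "fail"


class PresenceAbsenceGLM:
    """Binomial logit GLM on z-scored factors (the reference SDM).

    Parameters
    ----------
    train : TrainingTable
        Per-cell labels and raw-scale factor values.

    Constant-in-training factors are dropped (logged) before fitting;
    standardisation constants are estimated from the training data and
    travel with the fitted results so prediction uses the same scale.
    """

    model_kind = "glm"

    def __init__(self, train: TrainingTable):
        if train.n_presence == 0 or train.n_absence == 0:
            raise DegenerateTrainingError("both classes required")
        self.train = train
        sd = train.factors.std(ddof=0)
        self.dropped_constant = list(sd.index[sd == 0.0])
        if self.dropped_constant:
            logger.warning("dropping constant factors: %s", self.dropped_constant)
        self.factor_names = [n for n in train.factors.columns
                             if n not in self.dropped_constant]
        self.means = train.factors[self.factor_names].mean()
        self.sds = train.factors[self.factor_names].std(ddof=0)

    def _design(self, factors: pd.DataFrame) -> np.ndarray:
        Z = (factors[self.factor_names] - self.means) / self.sds
        return np.column_stack([np.ones(len(Z)), Z.to_numpy()])

    def fit(self, l2: float = 0.0, maxiter: int = 100) -> "SDMResults":
        """Fit by IRLS; ``l2 > 0`` adds a ridge penalty on the slopes.

        Raises :class:`SeparationError` if the classes are perfectly
        separable and no penalty was requested.
        """
        if l2 < 0:
            raise ParameterError("l2 penalty must be non-negative")
        y = self.train.labels
        X = self._design(self.train.factors)
        if l2 == 0.0:
            import warnings

            from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

            glm = sm.GLM(y, X, family=sm.families.Binomial())
            try:
                with warnings.catch_warnings(), np.errstate(all="ignore"):
                    warnings.simplefilter("error", PerfectSeparationWarning)
                    res = glm.fit(maxiter=maxiter)
            except Exception as exc:  # separation surfaces as warning or error
                if "separation" in str(exc).lower() or "Separation" in type(exc).__name__:
                    raise SeparationError(
                        "perfect separation detected; refit with l2 > 0"
                    ) from exc
                raise
            params = np.asarray(res.params)
            if not np.isfinite(params).all() or np.abs(params).max() > 1e4:
                raise SeparationError(
                    "diverging coefficients suggest (quasi-)separation; "
                    "refit with l2 > 0"
                )
            if not res.converged:
                raise ConvergenceError(f"IRLS did not converge in {maxiter} iterations")
            bse = np.asarray(res.bse)
            llf = float(res.llf)
            converged = bool(res.converged)
        else:
            # ridge-penalised Newton: maximise llf − (l2/2)·‖slopes‖²;
            # the penalty makes the Hessian positive definite even for a
            # perfectly collinear design, so full Newton steps converge
            D = np.ones(X.shape[1])
            D[0] = 0.0  # intercept unpenalised
            params = np.zeros(X.shape[1])
            converged = False
            for _ in range(maxiter):
                with np.errstate(over="ignore"):
                    p = 1.0 / (1.0 + np.exp(-(X @ params)))
                W = p * (1.0 - p)
                grad = X.T @ (y - p) - l2 * D * params
                H = (X.T * W) @ X + l2 * np.diag(D)
                step = np.linalg.solve(H, grad)
                params = params + step
                if np.abs(step).max() < 1e-10:
                    converged = True
                    break
            if not converged:
                raise ConvergenceError("penalised fit did not converge")
            with np.errstate(divide="ignore"):
                p = 1.0 / (1.0 + np.exp(-(X @ params)))
                llf = float(np.sum(np.where(y == 1, np.log(p), np.log1p(-p))))
            bse = np.full_like(params, np.nan)  # penalised SEs not reported
        eta = X @ params
        fitted = 1.0 / (1.0 + np.exp(-eta))
        train_auc = auc(y, fitted)
        return SDMResults(
            model=self,
            params=pd.Series(params, index=["intercept"] + self.factor_names),
            bse=pd.Series(bse, index=["intercept"] + self.factor_names),
            llf=llf,
            converged=converged,
            l2=l2,
            fitted=fitted,
            training_auc=train_auc,
        )


@dataclass
class SDMResults:
    """Fitted presence–absence model: coefficients, skill, and predictors.

    ``params`` are on the z-scored factor scale; ``raw_params`` rescales
    them to original factor units.
    """

    model: PresenceAbsenceGLM
    params: pd.Series
    bse: pd.Series
    llf: float
    converged: bool
    l2: float
    fitted: np.ndarray
    training_auc: float

    @property
    def model_kind(self) -> str:
        return self.model.model_kind

    @property
    def accuracy_band(self) -> str:
        return accuracy_band(self.training_auc)

    @property
    def raw_params(self) -> pd.Series:
        """Coefficients on the original factor scale (intercept adjusted)."""
        slopes = self.params.drop("intercept") / self.model.sds
        intercept = self.params["intercept"] - float(
            (self.params.drop("intercept") * self.model.means / self.model.sds).sum()
        )
        return pd.concat([pd.Series({"intercept": intercept}), slopes])

    def predict_table(self, factors: pd.DataFrame) -> np.ndarray:
        """Probabilities for a table of raw-scale factor values."""
        missing = [n for n in self.model.factor_names if n not in factors.columns]
        if missing:
            raise ContractError(f"missing factors: {missing}")
        X = self.model._design(factors)
        eta = X @ self.params.to_numpy()
        return 1.0 / (1.0 + np.exp(-eta))

    def predict(self, stack: FactorStack) -> RasterGrid:
        """Cellwise probability raster; nodata propagated from any layer."""
        missing = [n for n in self.model.factor_names if n not in stack]
        if missing:
            raise ContractError(f"stack is missing model factors: {missing}")
        template = stack.template
        ok = template.mask.copy()
        for n in self.model.factor_names:
            ok &= stack[n].mask
        idx = np.flatnonzero(ok.ravel())
        cols = {n: stack[n].values.ravel()[idx] for n in self.model.factor_names}
        p = self.predict_table(pd.DataFrame(cols))
        out = np.full(template.shape[0] * template.shape[1], np.nan)
        out[idx] = p
        return template.like(out.reshape(template.shape))

    def factor_importance(self, k: int = 5, seed: int = 0) -> pd.DataFrame:
        """Permutation importance: mean training-AUC drop over ``k`` shuffles
        of each factor column, ranked descending."""
        if k < 1:
            raise ParameterError("k must be at least 1")
        rng = np.random.default_rng(seed)
        y = self.model.train.labels
        base = self.training_auc
        rows = []
        factors = self.model.train.factors
        for name in self.model.factor_names:
            drops = []
            for _ in range(k):
                shuffled = factors.copy()
                shuffled[name] = rng.permutation(shuffled[name].to_numpy())
                drops.append(base - auc(y, self.predict_table(shuffled)))
            rows.append({"factor": name, "importance": float(np.mean(drops))})
        df = pd.DataFrame(rows).sort_values(
            "importance", ascending=False, kind="stable"
        )
        return df.reset_index(drop=True)

    def summary(self) -> str:
        """Human-readable fit summary (coefficients on the z-score scale)."""
        lines = [
            "Presence-absence GLM (binomial, logit link)",
            "=" * 55,
            f"n cells: {len(self.fitted)}   presence: {self.model.train.n_presence}"
            f"   absence: {self.model.train.n_absence}",
            f"log-likelihood: {self.llf:.2f}   converged: {self.converged}"
            f"   l2: {self.l2:g}",
            f"training AUC: {self.training_auc:.3f} ({self.accuracy_band})",
            "-" * 55,
            f"{'term':<28}{'coef':>12}{'std err':>12}",
        ]
        for name in self.params.index:
            se = self.bse[name]
            se_s = f"{se:>12.4f}" if np.isfinite(se) else f"{'—':>12}"
            lines.append(f"{name:<28}{self.params[name]:>12.4f}{se_s}")
        if self.model.dropped_constant:
            lines.append(f"dropped constant factors: {self.model.dropped_constant}")
        return "\n".join(lines)

    # -- serialisation ---------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "model_kind": self.model_kind,
            "params": self.params.to_dict(),
            "standardization": {
                "means": self.model.means.to_dict(),
                "sds": self.model.sds.to_dict(),
            },
            "l2": self.l2,
            "llf": self.llf,
            "converged": self.converged,
            "training_auc": self.training_auc,
            "accuracy_band": self.accuracy_band,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def select_model(candidates: list[SDMResults], threshold: float = 0.9) -> SDMResults:
    """The highest-AUC candidate clearing ``AUC > threshold``.

    Ties break to the earliest candidate in input order (logged). Raises
    :class:`SelectionError` listing every AUC when none qualifies.
    """
    if not candidates:
        raise ParameterError("need at least one candidate model")
    aucs = [c.training_auc for c in candidates]
    best_i, best = None, -np.inf
    for i, a in enumerate(aucs):
        if a > threshold and a > best:
            best_i, best = i, a
    if best_i is None:
        raise SelectionError(
            f"no candidate clears AUC > {threshold}; AUCs: "
            + ", ".join(f"{a:.3f}" for a in aucs)
        )
    if aucs.count(best) > 1:
        logger.info("AUC tie at %.3f; keeping first candidate in input order", best)
    return candidates[best_i]
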