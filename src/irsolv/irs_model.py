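"""Reorganization-energy regression: the IRS model family.

The solvation free energy is split as

    dG_sol = dG_int + dG_reo

where dG_int is the solute–solvent interaction free energy computed from the
trajectory (see :mod:`irsolv.interaction_thermo`) and the reorganization free
energy — cavity formation plus solvent restructuring — is approximated by a
polynomial expansion in dG_int together with a surface (or volume) term:

    dG_reo ≈ sum_k c_k * dG_int^{p_k} + gamma * SASA + b

The power sets define the model family: IRS1 {1}, IRS2 {1,2}, IRS3 {1,2,3},
IRS4 {1,2,3,4} and IRS(3/2) {1, 3/2}; IRS(3/2) is the default, giving the
best accuracy/generalization trade-off. The leading dG_int in dG_sol carries
fixed coefficient 1; the linear term inside the expansion is additional, so
the fit remains unrestricted. Coefficients are obtained by ordinary
multivariate least squares against experimental solvation energies
(response: dG_exp - dG_int).

Fractional powers of negative interaction energies (hydration dG_int is
typically negative) use the sign-preserving convention sign(x)·|x|^p; an
absolute-value convention is selectable per model spec for sensitivity
checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm

__all__ = [
    "MODEL_POWERS",
    "IRSDataset",
    "ModelSpec",
    "FittedModel",
    "Metrics",
    "signed_power",
    "design_matrix",
    "fit",
    "predict",
    "train_test_split",
    "evaluate",
    "decomposition_report",
]

MODEL_POWERS: dict[str, tuple[float, ...]] = {
    "IRS1": (1.0,),
    "IRS2": (1.0, 2.0),
    "IRS3": (1.0, 2.0, 3.0),
    "IRS4": (1.0, 2.0, 3.0, 4.0),
    "IRS3_2": (1.0, 1.5),
}

CONDITION_WARN_THRESHOLD = 1e8


class IRSDataset:
    """Per-solute table of (solute_id, dG_int, sasa[, dG_exp, dH_int, minus_TdS_int]).

    Thin wrapper over a :class:`pandas.DataFrame`; row order is meaningful
    and preserved by all operations.
    """

    REQUIRED = ("solute_id", "dG_int", "sasa")
    OPTIONAL = ("dG_exp", "dH_int", "minus_TdS_int")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"dataset missing required columns {missing}")
        for col in df.columns:
            if col == "solute_id":
                continue
            vals = df[col].to_numpy(float)
            if col in ("dG_int", "sasa") and not np.isfinite(vals).all():
                raise ValueError(f"column {col!r} contains non-finite values")
        if (df["sasa"].to_numpy(float) < 0).any():
            raise ValueError("sasa values must be >= 0")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def has_experimental(self) -> bool:
        return "dG_exp" in self.df.columns and self.df["dG_exp"].notna().all()

    @property
    def has_decomposition(self) -> bool:
        return all(c in self.df.columns for c in ("dH_int", "minus_TdS_int"))

    def column(self, name: str) -> np.ndarray:
        return self.df[name].to_numpy(float)

    @classmethod
    def from_arrays(cls, solute_id, dG_int, sasa, dG_exp=None, dH_int=None,
                    minus_TdS_int=None) -> "IRSDataset":
        data = {"solute_id": list(solute_id), "dG_int": dG_int, "sasa": sasa}
        if dG_exp is not None:
            data["dG_exp"] = dG_exp
        if dH_int is not None:
            data["dH_int"] = dH_int
        if minus_TdS_int is not None:
            data["minus_TdS_int"] = minus_TdS_int
        return cls(pd.DataFrame(data))

    def subset(self, indices) -> "IRSDataset":
        return IRSDataset(self.df.iloc[np.asarray(indices)].reset_index(drop=True))


@dataclass(frozen=True)
class ModelSpec:
    """One member of the IRS family: which powers of dG_int enter the expansion."""

    name: str = "IRS3_2"
    powers: tuple[float, ...] = ()
    include_sasa: bool = True
    include_intercept: bool = True
    power_convention: str = "signed"  # or "absolute"

    def __post_init__(self) -> None:
        if not self.powers:
            if self.name not in MODEL_POWERS:
                raise ValueError(
                    f"unknown model {self.name!r}; known: {sorted(MODEL_POWERS)}"
                )
            object.__setattr__(self, "powers", MODEL_POWERS[self.name])
        powers = tuple(float(p) for p in self.powers)
        if any(p < 1 for p in powers):
            raise ValueError("all powers must be >= 1")
        if list(powers) != sorted(set(powers)):
            raise ValueError("powers must be strictly increasing")
        object.__setattr__(self, "powers", powers)
        if self.power_convention not in ("signed", "absolute"):
            raise ValueError("power_convention must be 'signed' or 'absolute'")

    @property
    def n_parameters(self) -> int:
        return len(self.powers) + int(self.include_sasa) + int(self.include_intercept)


@dataclass(frozen=True)
class Metrics:
    """Agreement between predicted and observed solvation energies."""

    pearson_r: float
    mae: float
    rmse: float
    n: int


@dataclass
class FittedModel:
    """Fitted coefficients of one IRS variant.

    ``coefficients`` aligns with ``spec.powers``; ``gamma`` multiplies the
    SASA column (kcal/(mol·Å²) in SAS mode, per Å³ in SAV mode — the two are
    not comparable); ``b`` is the intercept (kcal/mol).
    """

    spec: ModelSpec
    coefficients: np.ndarray
    gamma: float
    b: float
    n_train: int
    training_metrics: Metrics | None = None
    stderr: np.ndarray | None = None  # full-parameter OLS standard errors
    condition_number: float | None = None

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (len(self.spec.powers),):
            raise ValueError("coefficient count must match the number of powers")
        if not np.isfinite(self.coefficients).all():
            raise ValueError("non-finite coefficients")

    def to_dict(self) -> dict:
        return {
            "spec": {
                "name": self.spec.name,
                "powers": list(self.spec.powers),
                "include_sasa": self.spec.include_sasa,
                "include_intercept": self.spec.include_intercept,
                "power_convention": self.spec.power_convention,
            },
            "coefficients": self.coefficients.tolist(),
            "gamma": self.gamma,
            "b": self.b,
            "n_train": self.n_train,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "FittedModel":
        spec = ModelSpec(
            name=doc["spec"]["name"],
            powers=tuple(doc["spec"]["powers"]),
            include_sasa=doc["spec"].get("include_sasa", True),
            include_intercept=doc["spec"].get("include_intercept", True),
            power_convention=doc["spec"].get("power_convention", "signed"),
        )
        return cls(
            spec=spec,
            coefficients=np.asarray(doc["coefficients"], dtype=float),
            gamma=float(doc["gamma"]),
            b=float(doc["b"]),
            n_train=int(doc["n_train"]),
        )


def signed_power(x: float, p: float, convention: str = "signed"):
    """|x|^p carrying the sign of x (default), or plain |x|^p.

    Keeps fractional powers real for the negative interaction energies typical
    of hydration. Integer exponents are evaluated as exact integer powers of
    |x|, so e.g. signed_power(-4, 2) == -16 under the signed convention.
    """
    x = np.asarray(x, dtype=float)
    p = float(p)
    if p < 1:
        raise ValueError("power must be >= 1")
    mag = np.abs(x) ** (int(p) if p == int(p) else p)
    out = mag if convention == "absolute" else np.sign(x) * mag
    return float(out) if out.ndim == 0 else out


def design_matrix(dataset: IRSDataset, spec: ModelSpec,
                  require_response: bool = True):
    """Build the regression design matrix and (optionally) the response.

    Columns: one per power of dG_int, then the SASA column and the intercept
    column when enabled. The response is y = dG_exp - dG_int, so the fitted
    linear combination models the reorganization free energy directly.

    Returns ``(X, y, column_names)``; ``y`` is None when
    ``require_response=False`` (prediction-time matrices).
    """
    dg_int = dataset.column("dG_int")
    cols = [signed_power(dg_int, p, spec.power_convention) for p in spec.powers]
    names = [f"dG_int^{p:g}" for p in spec.powers]
    if spec.include_sasa:
        cols.append(dataset.column("sasa"))
        names.append("sasa")
    if spec.include_intercept:
        cols.append(np.ones(len(dataset)))
        names.append("intercept")
    X = np.column_stack(cols)
    y = None
    if require_response:
        if "dG_exp" not in dataset.df.columns:
            raise ValueError("training dataset lacks a dG_exp column")
        exp = dataset.df["dG_exp"]
        if exp.isna().any():
            bad = dataset.df.index[exp.isna()].tolist()
            raise ValueError(f"rows {bad} lack dG_exp; cannot build training matrix")
        y = exp.to_numpy(float) - dg_int
    return X, y, names


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    # pivoted QR: columns with vanishing diagonal R entries are dependent
    _, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    return [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]


def fit(dataset: IRSDataset, spec: ModelSpec | None = None) -> FittedModel:
    """Ordinary least squares fit of one IRS variant to a training dataset.

    Raises on under-determined (n <= parameters) or rank-deficient designs
    (naming the collinear columns); warns when the design's condition number
    exceeds 1e8, which the quartic term can easily produce.
    """
    if spec is None:
        spec = ModelSpec()
    X, y, names = design_matrix(dataset, spec)
    n, p = X.shape
    if n <= p:
        raise ValueError(
            f"underdetermined fit: {n} rows for {p} free parameters"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValueError(
            f"rank-deficient design (rank {rank} < {p}); "
            f"collinear columns: {_collinear_columns(X, names)}"
        )
    cond = float(np.linalg.cond(X))
    if cond > CONDITION_WARN_THRESHOLD:
        warnings.warn(
            f"ill-conditioned design matrix (condition number {cond:.3g}); "
            "coefficients may be numerically unstable",
            UserWarning,
            stacklevel=2,
        )
    res = sm.OLS(y, X).fit()
    params = np.asarray(res.params, dtype=float)
    k = len(spec.powers)
    coeffs = params[:k]
    gamma = float(params[k]) if spec.include_sasa else 0.0
    b = float(params[-1]) if spec.include_intercept else 0.0
    model = FittedModel(
        spec=spec,
        coefficients=coeffs,
        gamma=gamma,
        b=b,
        n_train=n,
        stderr=np.asarray(res.bse, dtype=float),
        condition_number=cond,
    )
    pred = predict(model, dataset)
    model.training_metrics = evaluate(
        pred["dG_sol"].to_numpy(), dataset.column("dG_exp")
    )
    return model


def predict(model: FittedModel, dataset: IRSDataset) -> pd.DataFrame:
    """Per-row reorganization and solvation free energies.

    Returns a DataFrame with columns ``solute_id, dG_int, dG_reo, dG_sol``.
    """
    spec = model.spec
    X, _, _ = design_matrix(dataset, spec, require_response=False)
    params = list(model.coefficients)
    if spec.include_sasa:
        params.append(model.gamma)
    if spec.include_intercept:
        params.append(model.b)
    dg_reo = X @ np.asarray(params, dtype=float)
    dg_int = dataset.column("dG_int")
    return pd.DataFrame(
        {
            "solute_id": dataset.df["solute_id"],
            "dG_int": dg_int,
            "dG_reo": dg_reo,
            "dG_sol": dg_int + dg_reo,
        }
    )


def train_test_split(dataset: IRSDataset, test_fraction: float = 0.2,
                     seed: int = 0) -> tuple[IRSDataset, IRSDataset]:
    """Seeded random shuffle followed by a disjoint train/test split.

    The test size is round(n·test_fraction); with 353 rows and fraction
    73/353 this reproduces the canonical 280-train / 73-test protocol.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    n = len(dataset)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = int(round(n * test_fraction))
    if n_test == 0 or n_test == n:
        raise ValueError("split leaves an empty train or test set")
    return dataset.subset(np.sort(perm[n_test:])), dataset.subset(np.sort(perm[:n_test]))


def evaluate(predicted, observed) -> Metrics:
    """Pearson r, MAE and RMSE between predicted and observed energies.

    If either vector has zero variance the correlation is undefined: a
    UserWarning is emitted and ``pearson_r`` is NaN, while MAE/RMSE are still
    returned.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.ndim != 1:
        raise ValueError("predicted and observed must be 1-D of equal length")
    if predicted.size < 2:
        raise ValueError("need at least two points to evaluate")
    resid = observed - predicted
    mae = float(np.abs(resid).mean())
    rmse = float(np.sqrt((resid ** 2).mean()))
    if np.std(predicted) == 0 or np.std(observed) == 0:
        warnings.warn(
            "zero variance in predicted or observed values; Pearson r undefined",
            UserWarning,
            stacklevel=2,
        )
        r = float("nan")
    else:
        r = float(np.corrcoef(predicted, observed)[0, 1])
    return Metrics(pearson_r=r, mae=mae, rmse=rmse, n=predicted.size)


def decomposition_report(dataset: IRSDataset, model: FittedModel) -> pd.DataFrame:
    """Per-solute component table sorted by experimental solvation energy.

    Columns: interaction enthalpy, entropy term, each reorganization
    component (polynomial part, gamma·SASA, intercept), the assembled dG_sol,
    dG_exp and the signed error dG_exp - dG_sol. Components sum to dG_sol
    row-wise by construction.
    """
    needed = ("dH_int", "minus_TdS_int", "dG_exp")
    missing = [c for c in needed if c not in dataset.df.columns]
    if missing:
        raise ValueError(f"dataset lacks decomposition columns {missing}")
    for col in needed:
        if dataset.df[col].isna().any():
            bad = dataset.df.index[dataset.df[col].isna()].tolist()
            raise ValueError(f"rows {bad} lack {col}")
    dg_int = dataset.column("dG_int")
    consistency = np.abs(
        dataset.column("dH_int") + dataset.column("minus_TdS_int") - dg_int
    )
    if (consistency > 1e-6).any():
        bad = np.nonzero(consistency > 1e-6)[0].tolist()
        raise ValueError(f"rows {bad}: dH_int + minus_TdS_int != dG_int")

    spec = model.spec
    f_poly = sum(
        c * signed_power(dg_int, p, spec.power_convention)
        for c, p in zip(model.coefficients, spec.powers)
    )
    gamma_sasa = model.gamma * dataset.column("sasa") if spec.include_sasa else np.zeros(len(dataset))
    b = np.full(len(dataset), model.b if spec.include_intercept else 0.0)
    dg_sol = dg_int + f_poly + gamma_sasa + b
    report = pd.DataFrame(
        {
            "solute_id": dataset.df["solute_id"],
            "dH_int": dataset.column("dH_int"),
            "minus_TdS_int": dataset.column("minus_TdS_int"),
            "dG_int": dg_int,
            "f_poly": f_poly,
            "gamma_sasa": gamma_sasa,
            "b": b,
            "dG_sol": dg_sol,
            "dG_exp": dataset.column("dG_exp"),
        }
    )
    report["error"] = report["dG_exp"] - report["dG_sol"]
    return report.sort_values("dG_exp", kind="stable").reset_index(drop=True)
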