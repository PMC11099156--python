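"""Analytical fractal-Rouse prediction of nucleosome dynamics.

Chromatin is modeled as a Rouse polymer whose monomers (nucleosomes) are
arranged with fractal dimension ``d_f`` and diffuse in a viscoelastic
medium whose properties are probed by an inert tracer (HaloTag-NLS) with
anomalous exponent ``α_halo`` and apparent coefficient ``D_halo``.  The
model maps five independently measured quantities — α_halo, D_halo, and the
per-class fractal dimension d_f, nucleosome density ⟨ρ⟩ and squared domain
size ⟨R²⟩ — to the predicted nucleosome anomalous exponent and apparent
diffusion coefficient, with no free parameters:

    α_nuc = 2·α_halo / (2 + d_f)

    D_nuc = C · (3·D_free / ((4π/3)·⟨ρ⟩))^(2/(2+d_f)) · ⟨R²⟩^((d_f−3)/(d_f+2))

with D_free = D_halo·(R_halo/R_nuc) ≈ D_halo/5 (hydrodynamic radius ratio of
the tracer to a nucleosome) and the dimensionless constant

    C = 2·B / (A^(d_f/(2+d_f)) · Γ(1+α_halo)),
    A = π^(1+2/d_f) / (Γ(1+2/d_f)·sin(π/d_f)),
    B = (d_f/2) · Γ(1+α_halo)^(d_f/(2+d_f)) · Γ(d_f/(2+d_f)).

At d_f = 2, α_halo = 1 the exponent reduces to the classical Rouse value
1/2 and C = 2/√π.  Uncertainty on the predictions is propagated from the
measured uncertainties of α_halo and d_f by Monte Carlo (with a first-order
delta-method cross-check).

Units: D in µm²/s^α, ⟨ρ⟩ in µm⁻³, ⟨R²⟩ in µm² (nm² inputs are converted
explicitly — never silently).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gamma as Gamma

__all__ = [
    "ModelInputs",
    "ModelPrediction",
    "model_constants",
    "predict_alpha_nuc",
    "d_nuc_free",
    "predict_d_nuc",
    "propagate_errors",
    "compare_model_experiment",
    "nm2_to_um2",
]

NM2_PER_UM2 = 1e6


def nm2_to_um2(r2_nm2: float) -> float:
    """Explicit nm² → µm² conversion for squared domain sizes."""
    return r2_nm2 / NM2_PER_UM2


def _check_domain(d_f: float, alpha: float) -> None:
    # sin(π/d_f) must be strictly positive, which restricts d_f to (1, 3]
    if not (1 < d_f <= 3):
        raise ValueError(f"d_f={d_f} outside the model domain (1, 3]")
    if alpha <= 0:
        raise ValueError(f"alpha={alpha} must be positive")


def model_constants(d_f: float, alpha_halo: float) -> tuple[float, float, float]:
    """The dimensionless constants (A, B, C) of the fractal-Rouse map.

    Closed forms (Γ is the gamma function):
    ``A = π^(1+2/d_f)/(Γ(1+2/d_f)·sin(π/d_f))``,
    ``B = (d_f/2)·Γ(1+α)^(d_f/(2+d_f))·Γ(d_f/(2+d_f))``,
    ``C = 2B/(A^(d_f/(2+d_f))·Γ(1+α))``.
    """
    _check_domain(d_f, alpha_halo)
    A = math.pi ** (1.0 + 2.0 / d_f) / (Gamma(1.0 + 2.0 / d_f) * math.sin(math.pi / d_f))
    g1a = Gamma(1.0 + alpha_halo)
    expo = d_f / (2.0 + d_f)
    B = (d_f / 2.0) * g1a ** expo * Gamma(expo)
    C = 2.0 * B / (A ** expo * g1a)
    if not all(map(math.isfinite, (A, B, C))):
        raise ValueError("model constants non-finite in the requested domain")
    return float(A), float(B), float(C)


def predict_alpha_nuc(alpha_halo: float, d_f: float) -> float:
    """Predicted nucleosome anomalous exponent α_nuc = 2α_halo/(2+d_f).

    Strictly increasing in α_halo, strictly decreasing in d_f; equals the
    classical Rouse exponent 1/2 at α_halo = 1, d_f = 2.
    """
    _check_domain(d_f, alpha_halo)
    return 2.0 * alpha_halo / (2.0 + d_f)


def d_nuc_free(D_halo: float, radius_ratio: float = 1.0 / 5.0) -> float:
    """Free-nucleosome diffusion coefficient from the tracer's.

    Scales the measured tracer coefficient by the hydrodynamic radius ratio
    R_halo/R_nuc ≈ 1/5 of the tracer to a nucleosome.
    """
    if D_halo <= 0 or radius_ratio <= 0:
        raise ValueError("D_halo and radius_ratio must be positive")
    return D_halo * radius_ratio


def predict_d_nuc(
    alpha_halo: float,
    d_f: float,
    D_halo: float,
    rho_um3: float,
    R2_um2: float,
    radius_ratio: float = 1.0 / 5.0,
) -> float:
    """Predicted nucleosome apparent diffusion coefficient (µm²/s^α).

    ``rho_um3`` is the corrected nucleosome density in µm⁻³ and ``R2_um2``
    the mean squared chromatin-domain size in µm² (convert nm² inputs with
    :func:`nm2_to_um2`).  At d_f = 3 the domain-size exponent is exactly 0,
    so the prediction is independent of ⟨R²⟩ there.
    """
    _check_domain(d_f, alpha_halo)
    if rho_um3 <= 0 or R2_um2 <= 0:
        raise ValueError("density and domain size must be positive")
    _, _, C = model_constants(d_f, alpha_halo)
    D_free = d_nuc_free(D_halo, radius_ratio)
    core = (3.0 * D_free / ((4.0 * math.pi / 3.0) * rho_um3)) ** (2.0 / (2.0 + d_f))
    size = R2_um2 ** ((d_f - 3.0) / (d_f + 2.0))
    return float(C * core * size)


# ---------------------------------------------------------------------------
# Inputs / predictions with uncertainty
# ---------------------------------------------------------------------------

@dataclass
class ModelInputs:
    """Measured inputs of the model, per density class.

    ``d_f``, ``rho_um3`` and ``R2_um2`` map class label (1..K) to the
    per-class measurement; ``d_f_sd`` carries the propagated uncertainties.
    ``d_halo_convention`` records which coefficient convention D_halo uses
    (the log-log intercept by default).
    """

    alpha_halo: float
    alpha_halo_sd: float
    D_halo: float
    D_halo_sd: float = 0.0
    d_f: dict[int, float] = field(default_factory=dict)
    d_f_sd: dict[int, float] = field(default_factory=dict)
    rho_um3: dict[int, float] = field(default_factory=dict)
    R2_um2: dict[int, float] = field(default_factory=dict)
    radius_ratio: float = 1.0 / 5.0
    d_halo_convention: str = "loglog-intercept"

    def __post_init__(self) -> None:
        if not (0 < self.alpha_halo <= 2):
            raise ValueError("alpha_halo must lie in (0, 2]")
        if self.D_halo <= 0:
            raise ValueError("D_halo must be positive")
        for k, v in self.d_f.items():
            if not (1 < v <= 3):
                raise ValueError(f"d_f for class {k} outside the model domain (1, 3]")

    def mean_n_cd(self, k: int) -> float:
        """Mean nucleosome count per domain ⟨N⟩ = (4π/3)·⟨ρ⟩·⟨R⟩³."""
        R = math.sqrt(self.R2_um2[k])
        return (4.0 * math.pi / 3.0) * self.rho_um3[k] * R ** 3


@dataclass
class ModelPrediction:
    """Per-class predicted (α_nuc, D_nuc) with propagated uncertainty."""

    alpha_nuc: dict[int, float]
    alpha_nuc_sd: dict[int, float]
    D_nuc: dict[int, float]
    D_nuc_sd: dict[int, float]
    constants: dict[int, tuple[float, float, float]]
    D_nuc_free: float
    method: str = "monte-carlo"
    d_halo_convention: str = "loglog-intercept"


def _predict_class(inputs: ModelInputs, k: int,
                   alpha: float, d_f: float) -> tuple[float, float]:
    a = predict_alpha_nuc(alpha, d_f)
    D = predict_d_nuc(alpha, d_f, inputs.D_halo, inputs.rho_um3[k],
                      inputs.R2_um2[k], inputs.radius_ratio)
    return a, D


def propagate_errors(
    inputs: ModelInputs,
    n_mc: int = 10000,
    seed: int = 0,
    method: str = "monte-carlo",
) -> ModelPrediction:
    """Evaluate the model per class and propagate measurement uncertainty.

    Monte Carlo (default): sample ``(α_halo, d_f)`` from independent
    Gaussians truncated to the valid domain, evaluate the map, and report
    the mean and standard deviation of the draws.  ``method="delta"`` uses
    first-order (delta-method) propagation instead — useful as a
    cross-check; the Monte Carlo route is primary because the map is
    strongly nonlinear in d_f.
    """
    if method == "monte-carlo" and n_mc < 100:
        raise ValueError("n_mc must be >= 100")
    rng = np.random.default_rng(seed)
    classes = sorted(inputs.d_f)
    alpha_nuc, alpha_sd, d_nuc, d_sd, consts = {}, {}, {}, {}, {}
    for k in classes:
        a0, df0 = inputs.alpha_halo, inputs.d_f[k]
        sa, sdf = inputs.alpha_halo_sd, inputs.d_f_sd.get(k, 0.0)
        consts[k] = model_constants(df0, a0)
        if method == "monte-carlo":
            if sa == 0 and sdf == 0:
                a_mean, D_mean = _predict_class(inputs, k, a0, df0)
                a_std = D_std = 0.0
            else:
                a_draw = _truncated_normal(rng, a0, sa, 1e-3, 2.0, n_mc)
                d_draw = _truncated_normal(rng, df0, sdf, 1.0 + 1e-6, 3.0, n_mc)
                a_vals = 2.0 * a_draw / (2.0 + d_draw)
                D_vals = np.array([
                    predict_d_nuc(a, d, inputs.D_halo, inputs.rho_um3[k],
                                  inputs.R2_um2[k], inputs.radius_ratio)
                    for a, d in zip(a_draw, d_draw)
                ])
                a_mean, a_std = float(a_vals.mean()), float(a_vals.std())
                D_mean, D_std = float(D_vals.mean()), float(D_vals.std())
        elif method == "delta":
            a_mean, D_mean = _predict_class(inputs, k, a0, df0)
            eps_a = max(1e-6, 1e-4 * a0)
            eps_d = max(1e-6, 1e-4 * df0)
            da_dA = (predict_alpha_nuc(a0 + eps_a, df0)
                     - predict_alpha_nuc(a0 - eps_a, df0)) / (2 * eps_a)
            da_dD = (predict_alpha_nuc(a0, df0 + eps_d)
                     - predict_alpha_nuc(a0, df0 - eps_d)) / (2 * eps_d)
            dD_dA = (_predict_class(inputs, k, a0 + eps_a, df0)[1]
                     - _predict_class(inputs, k, a0 - eps_a, df0)[1]) / (2 * eps_a)
            dD_dD = (_predict_class(inputs, k, a0, df0 + eps_d)[1]
                     - _predict_class(inputs, k, a0, df0 - eps_d)[1]) / (2 * eps_d)
            a_std = math.hypot(da_dA * sa, da_dD * sdf)
            D_std = math.hypot(dD_dA * sa, dD_dD * sdf)
        else:
            raise ValueError(f"unknown method {method!r}")
        alpha_nuc[k], alpha_sd[k] = a_mean, a_std
        d_nuc[k], d_sd[k] = D_mean, D_std
    return ModelPrediction(
        alpha_nuc=alpha_nuc, alpha_nuc_sd=alpha_sd,
        D_nuc=d_nuc, D_nuc_sd=d_sd, constants=consts,
        D_nuc_free=d_nuc_free(inputs.D_halo, inputs.radius_ratio),
        method=method, d_halo_convention=inputs.d_halo_convention,
    )


def _truncated_normal(rng, mu, sd, lo, hi, n) -> np.ndarray:
    if sd == 0:
        return np.full(n, mu)
    out = rng.normal(mu, sd, n)
    bad = (out <= lo) | (out >= hi)
    while np.any(bad):
        out[bad] = rng.normal(mu, sd, int(bad.sum()))
        bad = (out <= lo) | (out >= hi)
    return out


def compare_model_experiment(
    pred: ModelPrediction,
    fits: list,
) -> pd.DataFrame:
    """Pair per-class predictions with measured interior fits.

    ``fits`` is a list of :class:`nucleodyn.tracking.PowerLawFit` restricted
    to the nuclear interior (periphery fits are rejected: lamina tethering
    is outside the model's scope).  Classes present on only one side are
    omitted with a warning.  Returns a long-format table with one row per
    (class, quantity) carrying predicted and measured values, uncertainties,
    and their ratio.
    """
    import warnings

    rows = []
    measured = {}
    for f in fits:
        if f.region not in ("interior", "whole-cell"):
            raise ValueError(
                f"fit for class {f.label} is from region {f.region!r}; "
                "only interior fits are comparable to the model")
        measured[f.label] = f
    for k in sorted(pred.D_nuc):
        if k not in measured:
            warnings.warn(f"class {k} missing from measured fits; omitted")
            continue
        f = measured[k]
        rows.append({"cdc": k, "quantity": "D",
                     "predicted": pred.D_nuc[k], "predicted_sd": pred.D_nuc_sd[k],
                     "measured": f.D_app,
                     "ratio": pred.D_nuc[k] / f.D_app})
        rows.append({"cdc": k, "quantity": "alpha",
                     "predicted": pred.alpha_nuc[k],
                     "predicted_sd": pred.alpha_nuc_sd[k],
                     "measured": f.alpha,
                     "ratio": pred.alpha_nuc[k] / f.alpha})
    return pd.DataFrame(rows)
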