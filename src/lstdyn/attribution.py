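"""Energy-balance attribution of LST changes to albedo and latent heat.

Linearizing the surface energy balance around the pre-loss state, a change
in outgoing long-wave radiation maps to an LST change through the
first-order Taylor sensitivity of εσLST⁴, i.e. 1/(4εσLST³) K per W m⁻².
Changes in absorbed shortwave due to albedo (−SW↓·Δα) and in latent heat
flux (−ΔLE) then convert into *equivalent* LST changes; downwelling
radiation, ground heat flux, and emissivity changes are taken as shared or
negligible between a loss pixel and its background controls.  Sensible heat
is never estimated from data: its equivalent contribution is the residual
ΔT − ΔT_α − ΔT_LE, so the three-way attribution is additive by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STEFAN_BOLTZMANN = 5.670374419e-8      # W m^-2 K^-4
SECONDS_PER_10_DAYS = 10 * 86400.0
DEFAULT_LAMBDA_V = 2.45e6              # latent heat of vaporization, J kg^-1


@dataclass
class EnergyBalanceInputs:
    """Pixel-level constants for the Taylor-expansion attribution.

    ``ref_lst`` and ``sw_down`` are pre-loss baseline-year means for the
    target pixel; ``emissivity`` is broadband surface emissivity (an input —
    supply a retrieval or use the 0.97 default).
    """

    ref_lst: float                     # K, pre-loss baseline-year mean
    sw_down: float                     # W m^-2, baseline-year mean
    emissivity: float = 0.97
    lambda_v: float = DEFAULT_LAMBDA_V

    def __post_init__(self) -> None:
        if not 0.0 < self.emissivity <= 1.0:
            raise ValueError("emissivity must be in (0, 1]")
        if self.ref_lst <= 0:
            raise ValueError("reference LST must be positive (kelvin)")
        if self.sw_down < 0:
            raise ValueError("SW down must be non-negative")


def taylor_sensitivity(emissivity: float, ref_lst: float) -> float:
    """Sensitivity of LST to a surface energy-flux perturbation, K/(W m⁻²).

    Equals 1/(4εσ·LST³): the inverse of the first-order Taylor term of
    upward long-wave radiation εσLST⁴.
    """
    if ref_lst <= 0:
        raise ValueError("reference LST must be positive")
    if not 0.0 < emissivity <= 1.0:
        raise ValueError("emissivity must be in (0, 1]")
    return 1.0 / (4.0 * emissivity * STEFAN_BOLTZMANN * ref_lst**3)


def et_to_le(delta_et, lambda_v: float = DEFAULT_LAMBDA_V):
    """Convert an ET change in mm per 10 days to a latent-heat flux in W m⁻².

    1 mm of water over 1 m² is 1 kg, so LE = ΔET·λ_v / (10·86400 s).
    """
    return np.asarray(delta_et, dtype=float) * lambda_v / SECONDS_PER_10_DAYS


def equivalent_dT(delta, inputs: EnergyBalanceInputs, kind: str):
    """Equivalent LST change (K) for an albedo or latent-heat change series.

    ``kind="albedo"``: Δ is unitless albedo change, contribution
    = sens·(−SW↓·Δα).  ``kind="latent"``: Δ is a latent-heat flux change in
    W m⁻², contribution = sens·(−ΔLE).
    """
    sens = taylor_sensitivity(inputs.emissivity, inputs.ref_lst)
    delta = np.asarray(delta, dtype=float)
    if kind == "albedo":
        return sens * (-inputs.sw_down * delta)
    if kind == "latent":
        return sens * (-delta)
    raise ValueError(f"unknown kind {kind!r} (expected 'albedo' or 'latent')")


@dataclass
class AttributionSeries:
    """Equivalent LST contributions for one paired sample.

    Yearly (trend) series are indexed by calendar year; monthly (seasonal)
    series by month 1–12.  ``dT_H``/``dS_H`` are residuals, so the
    attribution is exactly additive.
    """

    dT: pd.Series
    dT_alpha: pd.Series
    dT_le: pd.Series
    dT_h: pd.Series
    dS: pd.Series
    dS_alpha: pd.Series
    dS_le: pd.Series
    dS_h: pd.Series
    sensitivity: float                 # K per W m^-2


def attribute(dT: pd.Series, dS: pd.Series,
              d_alpha: pd.Series, d_et: pd.Series,
              dS_alpha_raw: pd.Series, dS_et_raw: pd.Series,
              inputs: EnergyBalanceInputs) -> AttributionSeries:
    """Convert albedo/ET change series into equivalent LST contributions.

    Parameters
    ----------
    dT, dS : Series
        Observed background-corrected LST changes (trend by year; seasonal
        by month).
    d_alpha, d_et : Series
        Background-corrected trend changes in albedo (unitless) and ET
        (mm/10 d), aligned to ``dT``'s years.
    dS_alpha_raw, dS_et_raw : Series
        Background-corrected monthly seasonal changes in albedo and ET.
    """
    sens = taylor_sensitivity(inputs.emissivity, inputs.ref_lst)
    dT_alpha = pd.Series(equivalent_dT(d_alpha.to_numpy(), inputs, "albedo"),
                         index=d_alpha.index)
    dT_le = pd.Series(
        equivalent_dT(et_to_le(d_et.to_numpy(), inputs.lambda_v), inputs, "latent"),
        index=d_et.index)
    dS_alpha = pd.Series(equivalent_dT(dS_alpha_raw.to_numpy(), inputs, "albedo"),
                         index=dS_alpha_raw.index)
    dS_le = pd.Series(
        equivalent_dT(et_to_le(dS_et_raw.to_numpy(), inputs.lambda_v), inputs, "latent"),
        index=dS_et_raw.index)
    return AttributionSeries(
        dT=dT, dT_alpha=dT_alpha, dT_le=dT_le,
        dT_h=dT - dT_alpha - dT_le,
        dS=dS, dS_alpha=dS_alpha, dS_le=dS_le,
        dS_h=dS - dS_alpha - dS_le,
        sensitivity=sens,
    )
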