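"""Synthetic fixtures: analytic excitation systems and QSPR tables.

Everything downstream of a TD-DFT run can be exercised without one.  Two
generators cover the two halves of the package:

* :func:`gaussian_excitation_fixture` builds a two-orbital excited state
  from analytic Gaussian orbitals whose centroids, spreads and separation
  have closed forms, so the descriptor engine can be checked against exact
  values rather than against itself.

* :func:`synthetic_qspr_table` emits a feature table with the production
  column manifest (40 quantum-chemistry + 24 structure + 6 metal + 3
  condition descriptors) whose target is a stated smooth function of a few
  "signal" descriptors plus Gaussian noise, squashed into (0, 1] by a
  logistic map.  The signal columns are recorded so recovery tests know the
  ground truth.  Regeneration under the same seed is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fields import ConfigurationSet
from .orbitals import GaussianOrbital, s_orbital
from .tables import ALL_DESCRIPTOR_COLUMNS, TARGET_COLUMN, default_manifest, FeatureTable

__all__ = ["ToyExcitationSystem", "gaussian_excitation_fixture", "synthetic_qspr_table"]


@dataclass(frozen=True)
class ToyExcitationSystem:
    """An analytic excitation with closed-form expected descriptor values."""

    orbitals: dict[int, GaussianOrbital]
    configs: ConfigurationSet
    centers: np.ndarray  # (2, 3), bohr
    energy_s1_ev: float
    energy_t1_ev: float
    dipole_length: np.ndarray
    dipole_velocity: np.ndarray
    dipole_magnetic: np.ndarray
    soc_cm1: float
    expected: dict[str, float] = field(default_factory=dict)  # closed-form values


def gaussian_excitation_fixture(
    separation: float = 4.0,
    exponent: float = 0.5,
    energy_s1_ev: float = 2.4,
    energy_t1_ev: float = 1.9,
    soc_cm1: float = 150.0,
) -> ToyExcitationSystem:
    """Hole on a Gaussian at the origin, electron on one ``separation`` bohr
    away along z; single excitation with w = 1.

    Closed forms: D = separation; every spread component is 1/(2 sqrt(a))
    for orbital exponent a, hence H_CT equals that same value (spreads are
    isotropic and equal) and t = D - H_CT.
    """
    if separation < 0:
        raise ValueError("separation must be nonnegative")
    centers = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, float(separation)]])
    orbitals = {0: s_orbital(centers[0], exponent), 1: s_orbital(centers[1], exponent)}
    configs = ConfigurationSet(((0, 1, 1.0),))
    sigma = 1.0 / (2.0 * np.sqrt(exponent))
    sigma_norm = sigma * np.sqrt(3.0)
    expected = {
        "d_bohr": float(separation),
        "sigma_axis_bohr": sigma,
        "sigma_norm_bohr": sigma_norm,
        "delta_sigma_bohr": 0.0,
        "hct_bohr": sigma if separation > 0 else 0.0,
        "h_bohr": sigma_norm,
        "t_bohr": float(separation) - (sigma if separation > 0 else 0.0),
        # int rho^2 dr for rho = (2a/pi)^{3/2} exp(-2 a r^2) is (a/pi)^{3/2}
        "hdi_as_printed": 100.0 * (exponent / np.pi) ** 1.5,
        "edi_as_printed": 100.0 * (exponent / np.pi) ** 1.5,
    }
    return ToyExcitationSystem(
        orbitals=orbitals,
        configs=configs,
        centers=centers,
        energy_s1_ev=energy_s1_ev,
        energy_t1_ev=energy_t1_ev,
        dipole_length=np.array([0.5, 0.0, 1.0]),
        dipole_velocity=np.array([0.4, 0.0, 0.9]),
        dipole_magnetic=np.array([0.0, 0.2, 0.0]),
        soc_cm1=soc_cm1,
        expected=expected,
    )


#: default descriptors carrying signal, chosen to span all four blocks
DEFAULT_SIGNAL = ("S-ee", "T-ee", "soc", "mw", "eps")

#: plausible (low, high) output ranges per descriptor column, used to place
#: generated values on realistic scales (affine maps; normalization undoes
#: them, so they are cosmetic for the models but keep tables readable)
_RANGES = {
    "S-ee": (1.8, 3.2), "T-ee": (1.4, 2.6), "soc": None,  # soc handled below
    "mw": (400.0, 1500.0), "eps": (2.0, 80.0), "epsinf": (1.7, 2.3),
    "wl": (350.0, 700.0), "an": (40.0, 160.0), "S1": (380.0, 690.0),
}


def _signal_function(z: np.ndarray) -> np.ndarray:
    """Smooth, mostly monotone target of the standardized signal columns.

    f(z) = 1.1 z1 + 0.9 z2 - 0.8 z3 + 0.7 z4 + 0.6 z5
           + 0.12 tanh(z4 z5) + 0.12 sin(pi z1 / 2)
    """
    return (
        1.1 * z[:, 0]
        + 0.9 * z[:, 1]
        - 0.8 * z[:, 2]
        + 0.7 * z[:, 3]
        + 0.6 * z[:, 4]
        + 0.12 * np.tanh(z[:, 3] * z[:, 4])
        + 0.12 * np.sin(0.5 * np.pi * z[:, 0])
    )


def synthetic_qspr_table(
    n: int = 136,
    noise_sigma: float = 0.05,
    seed: int = 0,
    signal_columns: tuple[str, ...] = DEFAULT_SIGNAL,
    echo_correlation: float = 0.7,
) -> FeatureTable:
    """A feature table shaped like the production dataset.

    The signal columns are independent latent factors drawn uniformly (wide
    support, as dominant descriptors have after normalization); every other
    descriptor column is an "echo" — a random signed mixture of the latent
    factors at correlation ``echo_correlation`` plus idiosyncratic noise —
    which emulates the strong collinearity of real descriptor blocks
    (S-/T-/D- triples, size measures, solvent constants).  The target is a
    stated smooth function of the latent factors plus Gaussian noise of
    ``noise_sigma`` times the signal's standard deviation, squashed into
    (0, 1] by the logistic map 1 / (1 + exp(-0.8 f)).

    All columns are continuous surrogates on plausible scales (the
    spin-orbit coupling is log-uniform so its log-transform is the latent
    value); integer-valued blocks are not discretized.  Regeneration under
    the same seed is byte-identical; the manifest records the generating
    conditions.
    """
    if n < 10:
        raise ValueError("need n >= 10")
    unknown = [c for c in signal_columns if c not in ALL_DESCRIPTOR_COLUMNS]
    if unknown:
        raise ValueError(f"signal column(s) not in the descriptor manifest: {unknown}")
    rng = np.random.default_rng(seed)
    nsig = len(signal_columns)
    latent = rng.uniform(-2.2, 2.2, size=(n, nsig))
    z = (latent - latent.mean(axis=0)) / latent.std(axis=0)

    def to_range(values: np.ndarray, col: str) -> np.ndarray:
        lo_hi = _RANGES.get(col)
        v01 = (values - values.min()) / (values.max() - values.min())
        if col == "soc":
            return 10.0 ** (v01 * 3.0)  # 1..1000 cm^-1, log scale
        if lo_hi is None:
            return values
        lo, hi = lo_hi
        return lo + v01 * (hi - lo)

    data: dict[str, np.ndarray] = {}
    sig_idx = {c: k for k, c in enumerate(signal_columns)}
    for col in ALL_DESCRIPTOR_COLUMNS:
        if col in sig_idx:
            data[col] = to_range(latent[:, sig_idx[col]], col)
        else:
            load = rng.dirichlet(np.ones(nsig)) * rng.choice([-1.0, 1.0], nsig)
            base = z @ load
            base = base / base.std()
            raw = echo_correlation * base + np.sqrt(1 - echo_correlation**2) * rng.normal(size=n)
            data[col] = to_range(raw, col)
    frame = pd.DataFrame(data, columns=list(ALL_DESCRIPTOR_COLUMNS))

    f = _signal_function(z)
    noise = rng.normal(0.0, noise_sigma * f.std(ddof=0), n)
    target = 1.0 / (1.0 + np.exp(-0.8 * (f + noise)))
    frame.insert(0, "identifier", [f"synthetic-{k:03d}" for k in range(n)])
    frame[TARGET_COLUMN] = target
    frame["metal_element"] = rng.choice(["Ru", "Ir", "Re"], n)
    frame["source"] = "internal"

    manifest = default_manifest()
    manifest["synthetic"] = {
        "seed": int(seed),
        "n": int(n),
        "noise_sigma_relative": float(noise_sigma),
        "signal_columns": list(signal_columns),
        "echo_correlation": float(echo_correlation),
        "squash": "logistic(0.8 * f)",
    }
    return FeatureTable(frame, manifest)
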