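"""Ground-truth kinetic model of the limonene-producing mevalonate pathway.

The model tracks ten metabolites — acetyl-CoA through the mevalonate
intermediates, IPP/DMAPP, GPP and limonene — driven by nine heterologous
enzymes (AtoB, HMGS, HMGR, MK, PMK, PMD, Idi, GPPS, LS). Every reaction is a
Michaelis–Menten-form rational function of its substrate, scaled linearly by
the catalysing enzyme's concentration:

    v = kcat * E * S / (Km + S)

with three deliberate elaborations: AtoB consumes two acetyl-CoA per
acetoacetyl-CoA formed, Idi is reversible (forward and reverse MM terms), and
GPPS condenses IPP with DMAPP through a dual-saturation term. Acetyl-CoA is
replenished by a constant source flux and drained by a first-order
consumption term, together standing in for host central metabolism (without
the drain, any supply in excess of pathway demand would pile up without
bound). Protein expression over a fermentation follows a saturating
"leaky Hill" profile

    p(t) = k_f * t / (k_m + t) + k_l

so each virtual strain is fully specified by one (k_f, k_m, k_l) triple per
enzyme; all strains in a pool share the same kinetic constants and differ
only in these expression profiles.

Units are arbitrary concentration units (a.u., order mM) and hours.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from scipy.integrate import solve_ivp

from .exceptions import InvalidParameterError, SimulationError, ValidationError
from .timeseries import OmicsTimeSeries

__all__ = [
    "METABOLITES",
    "PROTEINS",
    "HillProteinParams",
    "KineticParameters",
    "KineticModel",
    "StrainPool",
    "hill_profile",
    "simulate_strain",
    "generate_pool",
    "reference_parameters",
    "reference_hill_params",
    "default_sampling_ranges",
    "DEFAULT_TIMES",
    "DEFAULT_INITIAL_METABOLITES",
]

METABOLITES: tuple[str, ...] = (
    "acetyl-CoA",
    "acetoacetyl-CoA",
    "HMG-CoA",
    "mevalonate",
    "mevalonate-P",
    "mevalonate-PP",
    "IPP",
    "DMAPP",
    "GPP",
    "limonene",
)

PROTEINS: tuple[str, ...] = (
    "AtoB", "HMGS", "HMGR", "MK", "PMK", "PMD", "Idi", "GPPS", "LS",
)

#: experimental layout: seven samples over a 72 h fermentation
DEFAULT_TIMES = np.linspace(0.0, 72.0, 7)

#: a small acetyl-CoA pool at induction, all heterologous intermediates absent
DEFAULT_INITIAL_METABOLITES = np.array(
    [0.5, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0]
)

DEFAULT_BOUNDS = (1e-12, 1e9)

PARAMETER_NAMES: tuple[str, ...] = (
    "acetyl_coa_supply",
    "acetyl_coa_decay",
    "AtoB_kcat", "AtoB_km",
    "HMGS_kcat", "HMGS_km",
    "HMGR_kcat", "HMGR_km",
    "MK_kcat", "MK_km",
    "PMK_kcat", "PMK_km",
    "PMD_kcat", "PMD_km",
    "Idi_kcat_f", "Idi_km_f", "Idi_kcat_r", "Idi_km_r",
    "GPPS_kcat", "GPPS_km_ipp", "GPPS_km_dmapp",
    "LS_kcat", "LS_km",
)


@dataclass(frozen=True)
class HillProteinParams:
    """Leaky-Hill expression profile coefficients for one protein.

    k_f is the saturating amplitude (a.u.), k_m the half-saturation time
    (hours), and k_l the leak (basal expression, a.u.).
    """

    k_f: float
    k_m: float
    k_l: float

    def __post_init__(self):
        if self.k_m <= 0:
            raise InvalidParameterError(f"k_m must be positive, got {self.k_m}")
        if self.k_f < 0 or self.k_l < 0:
            raise InvalidParameterError("k_f and k_l must be nonnegative")


def hill_profile(params: HillProteinParams, times: np.ndarray) -> np.ndarray:
    """Evaluate the leaky Hill expression profile p(t) = k_f*t/(k_m+t) + k_l."""
    t = np.asarray(times, dtype=float)
    if t.size and (np.any(t < 0) or np.any(np.diff(t) <= 0)):
        raise ValidationError("times must be nonnegative and strictly increasing")
    return params.k_f * t / (params.k_m + t) + params.k_l


@dataclass
class KineticParameters:
    """Named kinetic constants with box bounds.

    Constants must be strictly positive and inside their bounds; bounds
    default to the wide search box [1e-12, 1e9] used when fitting.
    """

    values: dict[str, float]
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        missing = set(PARAMETER_NAMES) - set(self.values)
        extra = set(self.values) - set(PARAMETER_NAMES)
        if missing or extra:
            raise InvalidParameterError(
                f"kinetic parameter names mismatch: missing={sorted(missing)}, "
                f"unknown={sorted(extra)}"
            )
        for name in PARAMETER_NAMES:
            lo, hi = self.bounds.get(name, DEFAULT_BOUNDS)
            self.bounds[name] = (lo, hi)
            v = self.values[name]
            if not (v > 0 and np.isfinite(v)):
                raise InvalidParameterError(f"{name} must be strictly positive, got {v}")
            if not (lo <= v <= hi):
                raise InvalidParameterError(
                    f"{name}={v} outside its bounds [{lo}, {hi}]"
                )

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def to_vector(self) -> np.ndarray:
        return np.array([self.values[n] for n in PARAMETER_NAMES])

    @classmethod
    def from_vector(cls, vec: np.ndarray,
                    bounds: dict[str, tuple[float, float]] | None = None
                    ) -> "KineticParameters":
        return cls(dict(zip(PARAMETER_NAMES, map(float, vec))),
                   dict(bounds) if bounds else {})


def _mm(kcat: float, enzyme: float, substrate: float, km: float) -> float:
    return kcat * enzyme * substrate / (km + substrate)


class KineticModel:
    """The 10-state mevalonate/limonene ODE system.

    The right-hand side contract is ``rhs(t, m, p) -> dm/dt`` where ``m`` is
    the 10-vector of metabolite concentrations and ``p`` the 9-vector of
    enzyme concentrations (ordered as :data:`PROTEINS`). States are clipped
    at zero inside the RHS so adaptive-integration overshoot cannot push a
    Michaelis–Menten term below its domain.
    """

    metabolite_names = METABOLITES
    protein_names = PROTEINS

    def __init__(self, params: KineticParameters):
        self.params = params

    # -- kinetics ------------------------------------------------------

    def fluxes(self, m: np.ndarray, p: np.ndarray) -> dict[str, float]:
        """Per-reaction fluxes at state ``m`` with enzyme levels ``p``."""
        m = np.clip(np.asarray(m, dtype=float), 0.0, None)
        k = self.params
        acoa, aacoa, hmgcoa, mev, mevp, mevpp, ipp, dmapp, gpp, _lim = m
        atob, hmgs, hmgr, mk, pmk, pmd, idi, gpps, ls = p
        return {
            "supply": k["acetyl_coa_supply"],
            "decay": k["acetyl_coa_decay"] * acoa,
            "AtoB": _mm(k["AtoB_kcat"], atob, acoa, k["AtoB_km"]),
            "HMGS": _mm(k["HMGS_kcat"], hmgs, aacoa, k["HMGS_km"]),
            "HMGR": _mm(k["HMGR_kcat"], hmgr, hmgcoa, k["HMGR_km"]),
            "MK": _mm(k["MK_kcat"], mk, mev, k["MK_km"]),
            "PMK": _mm(k["PMK_kcat"], pmk, mevp, k["PMK_km"]),
            "PMD": _mm(k["PMD_kcat"], pmd, mevpp, k["PMD_km"]),
            "Idi": (_mm(k["Idi_kcat_f"], idi, ipp, k["Idi_km_f"])
                    - _mm(k["Idi_kcat_r"], idi, dmapp, k["Idi_km_r"])),
            "GPPS": (k["GPPS_kcat"] * gpps
                     * ipp / (k["GPPS_km_ipp"] + ipp)
                     * dmapp / (k["GPPS_km_dmapp"] + dmapp)),
            "LS": _mm(k["LS_kcat"], ls, gpp, k["LS_km"]),
        }

    def rhs(self, t: float, m: np.ndarray, p: np.ndarray) -> np.ndarray:
        v = self.fluxes(m, p)
        return np.array([
            v["supply"] - v["decay"] - 2.0 * v["AtoB"],  # acetyl-CoA
            v["AtoB"] - v["HMGS"],                  # acetoacetyl-CoA
            v["HMGS"] - v["HMGR"],                  # HMG-CoA
            v["HMGR"] - v["MK"],                    # mevalonate
            v["MK"] - v["PMK"],                     # mevalonate-P
            v["PMK"] - v["PMD"],                    # mevalonate-PP
            v["PMD"] - v["Idi"] - v["GPPS"],        # IPP
            v["Idi"] - v["GPPS"],                   # DMAPP
            v["GPPS"] - v["LS"],                    # GPP
            v["LS"],                                # limonene (terminal sink)
        ])


@dataclass
class StrainPool:
    """A pool of virtual strains sharing kinetic constants.

    Strains differ only in their Hill protein-expression profiles; each
    carries its simulated time series and final product (limonene) titre.
    """

    model: KineticModel
    hill_params: list[dict[str, HillProteinParams]]
    series: list[OmicsTimeSeries]
    final_products: np.ndarray
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.series)


def simulate_strain(
    model: KineticModel,
    proteins: dict[str, HillProteinParams],
    initial_metabolites: np.ndarray = DEFAULT_INITIAL_METABOLITES,
    times: np.ndarray = DEFAULT_TIMES,
    strain_id: str = "virtual",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> OmicsTimeSeries:
    """Simulate one strain's multiomics time series.

    The metabolite ODE system is integrated with adaptive RK45 from the given
    nonnegative initial state; enzyme concentrations at any interior solver
    time come from the closed-form Hill profiles, so no interpolation error
    enters the ground truth. Output concentrations are clipped at zero.
    """
    times = np.asarray(times, dtype=float)
    m0 = np.asarray(initial_metabolites, dtype=float)
    if np.any(m0 < 0):
        raise ValidationError("initial metabolite concentrations must be nonnegative")
    if len(m0) != len(model.metabolite_names):
        raise ValidationError(
            f"expected {len(model.metabolite_names)} initial metabolites, got {len(m0)}"
        )
    missing = set(model.protein_names) - set(proteins)
    if missing:
        raise ValidationError(f"missing Hill parameters for proteins {sorted(missing)}")
    hp = [proteins[name] for name in model.protein_names]

    def protein_vector(t: float) -> np.ndarray:
        return np.array([h.k_f * t / (h.k_m + t) + h.k_l for h in hp])

    def f(t, m):
        return model.rhs(t, np.clip(m, 0.0, None), protein_vector(t))

    sol = solve_ivp(
        f, (times[0], times[-1]), m0, method="RK45",
        t_eval=times, rtol=rtol, atol=atol,
    )
    if not sol.success:
        t_fail = sol.t[-1] if sol.t.size else times[0]
        raise SimulationError(
            f"RK45 integration failed near t={t_fail:.3f} h: {sol.message}",
            time=float(t_fail),
        )
    mets = np.clip(sol.y.T, 0.0, None)
    prots = np.stack([hill_profile(h, times) for h in hp], axis=1)
    return OmicsTimeSeries(
        strain_id=strain_id,
        times=times,
        metabolites=mets,
        proteins=prots,
        metabolite_names=model.metabolite_names,
        protein_names=model.protein_names,
    )


def generate_pool(
    model: KineticModel,
    pool_size: int,
    sampling_ranges: dict[str, dict[str, tuple[float, float]]] | None = None,
    seed: int | None = None,
    initial_metabolites: np.ndarray = DEFAULT_INITIAL_METABOLITES,
    times: np.ndarray = DEFAULT_TIMES,
) -> StrainPool:
    """Generate a pool of virtual strains with random Hill protein profiles.

    Hill coefficients are drawn log-uniformly and independently per protein
    within `sampling_ranges` (defaults span two orders of magnitude around
    the reference expression levels). All strains share the model's kinetic
    constants; the pool records each strain's final limonene titre for
    ranking experiments. Reproducible under a fixed seed.
    """
    if pool_size < 1:
        raise ValidationError("pool_size must be >= 1")
    ranges = sampling_ranges or default_sampling_ranges()
    rng = np.random.default_rng(seed)
    product_idx = model.metabolite_names.index("limonene")
    hill_sets: list[dict[str, HillProteinParams]] = []
    series: list[OmicsTimeSeries] = []
    finals = np.empty(pool_size)
    for i in range(pool_size):
        strain_params: dict[str, HillProteinParams] = {}
        for name in model.protein_names:
            r = ranges[name]
            strain_params[name] = HillProteinParams(
                k_f=_log_uniform(rng, *r["k_f"]),
                k_m=_log_uniform(rng, *r["k_m"]),
                k_l=_log_uniform(rng, *r["k_l"]),
            )
        s = simulate_strain(
            model, strain_params, initial_metabolites, times,
            strain_id=f"virtual-{i:05d}",
        )
        hill_sets.append(strain_params)
        series.append(s)
        finals[i] = s.metabolites[-1, product_idx]
    return StrainPool(model=model, hill_params=hill_sets, series=series,
                      final_products=finals, seed=seed)


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    if not (0 < lo <= hi):
        raise ValidationError(f"sampling range must be positive, got [{lo}, {hi}]")
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


# -- reference configuration ------------------------------------------


def _load_reference_config() -> dict:
    with resources.files("pathdyn.data").joinpath("reference_model.yaml").open() as fh:
        return yaml.safe_load(fh)


def reference_parameters(path: str | Path | None = None) -> KineticParameters:
    """The package's named reference kinetic constants.

    Chosen so the default 72 h fermentation shows non-trivial dynamics: an
    early acetyl-CoA transient and a peak-then-decline in IPP/DMAPP as the
    downstream condensation and synthase capacity ramps up.
    """
    cfg = yaml.safe_load(Path(path).read_text()) if path else _load_reference_config()
    return KineticParameters({k: float(v) for k, v in cfg["kinetic_constants"].items()})


def reference_hill_params(path: str | Path | None = None) -> dict[str, HillProteinParams]:
    """Reference (medium-producer-like) Hill expression profiles per enzyme."""
    cfg = yaml.safe_load(Path(path).read_text()) if path else _load_reference_config()
    return {
        name: HillProteinParams(**{k: float(v) for k, v in triple.items()})
        for name, triple in cfg["reference_hill"].items()
    }


def default_sampling_ranges(
    path: str | Path | None = None,
) -> dict[str, dict[str, tuple[float, float]]]:
    """Log-uniform sampling ranges for pool generation, per protein."""
    cfg = yaml.safe_load(Path(path).read_text()) if path else _load_reference_config()
    out: dict[str, dict[str, tuple[float, float]]] = {}
    for name, triples in cfg["sampling_ranges"].items():
        out[name] = {k: (float(v[0]), float(v[1])) for k, v in triples.items()}
    return out
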