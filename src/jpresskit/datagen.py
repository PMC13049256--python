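"""Synthetic JPRESS sample generation.

Assembles training/test samples from the unit-concentration basis:
random concentrations (uniform, metabolite-specific medians), subgroup T2s
perturbed by a shared global rate offset plus per-subgroup offsets, a
modified-Voigt lineshape shared by all echoes, independent per-echo phase
and frequency offsets, an independently perturbed residual water signal,
per-metabolite chemical-shift jitter, complex white noise, and damped
extraneous peaks.  Every component FID and every label is recorded, and the
input equals the sum of components plus background exactly by construction.
"""

from __future__ import annotations

import json
import hashlib
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import h5py
import yaml

from .simulator import AcquisitionGrid, BasisFid, BasisSet

__all__ = [
    "DEFAULT_MEDIANS_MM", "COMPONENT_GROUPS", "GenConfig", "ConcentrationPrior",
    "LineshapePFL", "JpressSample", "SampleGenerator",
    "eval_lineshape", "assign_t2", "average_t2",
    "apply_relaxation_and_lineshape", "add_noise_and_artifacts",
    "generate_dataset", "load_dataset",
]

logger = logging.getLogger(__name__)

# Medians (mM) of the uniform concentration priors, one per metabolite.
DEFAULT_MEDIANS_MM = {
    "NAA": 10.0, "NAAG": 5.0, "Cr": 5.0, "PCr": 5.0, "PCho": 5.0, "GPCho": 5.0,
    "Glu": 10.0, "Gln": 10.0, "GSH": 10.0, "Tau": 10.0, "Asp": 10.0,
    "mI": 10.0, "GABA": 10.0, "Lac": 10.0,
}

# Canonical 12 output components: combined metabolites first, water last.
COMPONENT_GROUPS = {
    "tNAA": ["NAA", "NAAG"], "tCr": ["Cr", "PCr"], "tCho": ["PCho", "GPCho"],
    "Glu": ["Glu"], "Gln": ["Gln"], "GSH": ["GSH"], "Tau": ["Tau"],
    "Asp": ["Asp"], "mI": ["mI"], "GABA": ["GABA"], "Lac": ["Lac"],
    "water": ["water"],
}


@dataclass
class GenConfig:
    """All randomized ranges of the generative model.

    T2 offsets delta1/delta2 are rate offsets in 1/s added to the preset
    subgroup relaxation rate; metabolite subgroup presets are drawn so that
    realized metabolite T2s span roughly 90-590 ms and water 75-1400 ms.
    """

    medians_mm: dict = field(default_factory=lambda: dict(DEFAULT_MEDIANS_MM))
    conc_cap_mm: float = 20.0
    met_delta1: tuple = (-1.3, 4.4)        # 1/s, shared by all metabolites
    water_delta1: tuple = (1.3, 12.6)      # 1/s, independent
    delta2: tuple = (-0.63, 0.63)          # 1/s, per subgroup
    met_preset_t2: tuple = (0.164, 0.276)  # s; preset rate uniform in 1/range
    water_preset_inv_t2: float = 0.044     # 1/s
    lorentzian: tuple = (np.pi, 8 * np.pi)  # 1/s
    gaussian: tuple = (9.0, 21.0)           # 1/s^2
    b1: tuple = (-1.5, 3.0)                 # 1/s
    b2: tuple = (-3.0, 30.0)                # 1/s^2
    b3: tuple = (0.0, 210.0)                # 1/s^3
    phase_deg: tuple = (0.0, 360.0)         # per TE
    freq_offset_hz: tuple = (-5.0, 5.0)     # per TE
    shift_jitter_hz: tuple = (-1.0, 1.0)    # per metabolite
    water_amp_ratio: tuple = (0.5, 50.0)    # log-uniform, x total metabolite amp
    noise_sigma: tuple = (0.2, 2.0)         # log-uniform, simulator units
    max_artifacts: int = 8
    artifact_amp_ratio: float = 2.0         # x largest metabolite first point
    artifact_damping: tuple = (5.0, 100.0)  # 1/s
    t2_weighted_average: bool = True        # proton-signal-weighted combined label

    def to_yaml(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(d)), fh)

    @classmethod
    def from_yaml(cls, path) -> "GenConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls()
        for k, v in raw.items():
            if not hasattr(cfg, k):
                raise ValueError(f"unknown config key {k!r}")
            cur = getattr(cfg, k)
            setattr(cfg, k, tuple(v) if isinstance(cur, tuple) else v)
        return cfg

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ConcentrationPrior:
    """Uniform concentration priors on [0, 2 x median] per metabolite."""

    medians_mm: dict = field(default_factory=lambda: dict(DEFAULT_MEDIANS_MM))
    cap_mm: float = 20.0

    def draw(self, metabolites: list[str], rng: np.random.Generator) -> dict:
        out = {}
        for met in metabolites:
            m = self.medians_mm[met]
            hi = min(2.0 * m, self.cap_mm)
            out[met] = float(rng.uniform(0.0, hi))
        return out

    def draw_many(self, metabolite: str, n: int,
                  rng: np.random.Generator) -> np.ndarray:
        """Vectorized draws for one metabolite."""
        m = self.medians_mm[metabolite]
        return rng.uniform(0.0, min(2.0 * m, self.cap_mm), size=n)


@dataclass
class LineshapePFL:
    """Modified-Voigt lineshape plus per-echo phase/frequency draws."""

    lam: float                 # Lorentzian damping, 1/s
    g: float                   # Gaussian damping, 1/s^2
    b1: float                  # 1/s
    b2: float                  # 1/s^2
    b3: float                  # 1/s^3
    phases_deg: np.ndarray     # per TE, degrees
    freq_offsets_hz: np.ndarray  # per TE, Hz

    @classmethod
    def draw(cls, n_te: int, cfg: GenConfig, rng: np.random.Generator) -> "LineshapePFL":
        return cls(
            lam=float(rng.uniform(*cfg.lorentzian)),
            g=float(rng.uniform(*cfg.gaussian)),
            b1=float(rng.uniform(*cfg.b1)),
            b2=float(rng.uniform(*cfg.b2)),
            b3=float(rng.uniform(*cfg.b3)),
            phases_deg=rng.uniform(*cfg.phase_deg, size=n_te),
            freq_offsets_hz=rng.uniform(*cfg.freq_offset_hz, size=n_te),
        )

    def envelope(self, t: np.ndarray) -> np.ndarray:
        return eval_lineshape(t, self)

    def phase_factors(self, t: np.ndarray) -> np.ndarray:
        """exp(i(phase_te + 2 pi f_te t)), shape (n_te, len(t))."""
        phi = np.deg2rad(self.phases_deg)[:, None]
        return np.exp(1j * (phi + 2 * np.pi * self.freq_offsets_hz[:, None] * t[None, :]))


def eval_lineshape(t: np.ndarray, p: LineshapePFL) -> np.ndarray:
    """Modified Voigt: exp(-lam t - g t^2) (1 - b1 t - b2 t^2 - b3 t^3).

    Equals 1 at t=0; the cubic factor may go negative at large t and is
    retained as an amplitude modulation (no clipping).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("lineshape is defined for t >= 0")
    return np.exp(-p.lam * t - p.g * t ** 2) * (1 - p.b1 * t - p.b2 * t ** 2 - p.b3 * t ** 3)


def assign_t2(preset_inv_t2: float, delta1: float, delta2: float) -> float:
    """Realized subgroup T2 (s): 1 / (preset rate + delta1 + delta2)."""
    total = preset_inv_t2 + delta1 + delta2
    if total <= 0:
        raise ValueError("non-positive total relaxation rate")
    return 1.0 / total


def average_t2(subgroup_t2s) -> float:
    """Metabolite-level average T2: arithmetic mean over subgroups."""
    arr = np.asarray(subgroup_t2s, dtype=float)
    if arr.size == 0:
        raise ValueError("average_t2 of an empty list")
    return float(arr.mean())


def apply_relaxation_and_lineshape(basis: BasisFid, t2: float, p: LineshapePFL,
                                   te: float | None = None,
                                   te_index: int = 0) -> np.ndarray:
    """T2-attenuate and PFL-modulate one basis FID.

    T2 attenuates both the echo delay and the acquisition window; the
    lineshape applies to acquisition time only (inhomogeneity refocused at
    the echo); phase and frequency offset are those of ``te_index``.
    """
    if te is None:
        te = basis.te
    if basis.dwell_time <= 0:
        raise ValueError("basis needs a positive dwell_time for the time axis")
    t = np.arange(len(basis.samples)) * basis.dwell_time
    decay = np.exp(-(te + t) / t2)
    phase = np.exp(1j * (np.deg2rad(p.phases_deg[te_index])
                         + 2 * np.pi * p.freq_offsets_hz[te_index] * t))
    return basis.samples * decay * eval_lineshape(t, p) * phase


def add_noise_and_artifacts(clean: np.ndarray, rng: np.random.Generator,
                            cfg: GenConfig, grid: AcquisitionGrid,
                            reference_amplitude: float = 1.0):
    """Complex white noise plus damped complex-exponential extraneous peaks.

    Returns ``(clean + background, background)``; artifact frequencies and
    dampings are fixed across echoes while their phases and amplitudes vary
    per echo.  ``reference_amplitude`` scales the artifact amplitude cap.
    """
    n_te, n_points = clean.shape
    t = grid.times
    lo, hi = cfg.noise_sigma
    sigma = float(np.exp(rng.uniform(np.log(lo), np.log(hi)))) if lo > 0 else float(hi)
    background = sigma * (rng.standard_normal(clean.shape)
                          + 1j * rng.standard_normal(clean.shape))
    k = int(rng.integers(0, cfg.max_artifacts + 1)) if cfg.max_artifacts > 0 else 0
    sw = grid.spectral_width
    for _ in range(k):
        freq = rng.uniform(-sw / 2, sw / 2)
        damp = rng.uniform(*cfg.artifact_damping)
        base = rng.uniform(0, cfg.artifact_amp_ratio * reference_amplitude)
        amps = base * rng.uniform(0.5, 1.0, size=n_te)
        phases = rng.uniform(0, 2 * np.pi, size=n_te)
        background = background + (
            amps[:, None] * np.exp(1j * phases[:, None])
            * np.exp((1j * 2 * np.pi * freq - damp) * t)[None, :]
        )
    return clean + background, background


@dataclass
class JpressSample:
    """One synthetic multi-echo sample with all components and labels."""

    input: np.ndarray            # (n_te, n_points) complex
    component_fids: np.ndarray   # (n_comp, n_te, n_points) complex
    background: np.ndarray       # (n_te, n_points) complex
    concentrations: np.ndarray   # (n_comp,) mM; combined = sum of constituents
    avg_t2: np.ndarray           # (n_comp,) s
    amplitudes: np.ndarray       # (n_te, n_comp) first-point magnitudes
    component_names: list[str]
    meta: dict = field(default_factory=dict)

    def as_channels(self) -> np.ndarray:
        """Input serialized as (n_te, n_points, 2) float."""
        return np.stack([self.input.real, self.input.imag], axis=-1)


class SampleGenerator:
    """Draws complete JPRESS samples from a basis set and a config."""

    def __init__(self, basis: BasisSet, cfg: GenConfig | None = None,
                 systems: dict | None = None):
        from .spins import builtin_systems
        self.basis = basis
        self.cfg = cfg or GenConfig()
        self.grid = basis.grid
        all_systems = systems or builtin_systems()
        present = set(basis.metabolites)
        self.systems = {m: all_systems[m] for m in all_systems if m in present}
        self.metabolites = [m for m in self.systems if m != "water"]
        if "water" not in present:
            raise ValueError("basis must include water")
        self.components = [
            (comp, [m for m in mets if m in present])
            for comp, mets in COMPONENT_GROUPS.items()
            if any(m in present for m in mets)
        ]
        self.component_names = [c for c, _ in self.components]
        self.prior = ConcentrationPrior(self.cfg.medians_mm, self.cfg.conc_cap_mm)

    @property
    def n_components(self) -> int:
        return len(self.components)

    def rng_for(self, seed: int, index: int) -> np.random.Generator:
        """Counter-derived per-sample stream: order-independent datasets."""
        return np.random.default_rng(np.random.SeedSequence([int(seed), int(index)]))

    def _draw_t2s(self, rng: np.random.Generator):
        """Subgroup T2s (s) keyed (metabolite, subgroup); water included."""
        cfg = self.cfg
        delta1 = float(rng.uniform(*cfg.met_delta1))
        water_delta1 = float(rng.uniform(*cfg.water_delta1))
        lo_rate = 1.0 / cfg.met_preset_t2[1]
        hi_rate = 1.0 / cfg.met_preset_t2[0]
        t2s: dict[tuple[str, str], float] = {}
        for met, system in self.systems.items():
            d1 = water_delta1 if met == "water" else delta1
            for sg in system.subgroups:
                preset = (cfg.water_preset_inv_t2 if met == "water"
                          else float(rng.uniform(lo_rate, hi_rate)))
                for _ in range(100):
                    d2 = float(rng.uniform(*cfg.delta2))
                    if preset + d1 + d2 > 0:
                        break
                    logger.warning("redrawing delta2 for %s/%s", met, sg)
                t2s[(met, sg)] = assign_t2(preset, d1, d2)
        return t2s, delta1, water_delta1

    def _metabolite_fid(self, met: str, conc: float, t2s, pfl: LineshapePFL,
                        jitter_hz: float) -> np.ndarray:
        """(n_te, n_points) FID of one metabolite after all augmentation."""
        grid = self.grid
        t = grid.times
        te = grid.te_values[:, None]
        out = np.zeros((grid.n_te, grid.n_points), dtype=complex)
        for sg in self.basis.subgroups_of(met):
            arr = self.basis.fids[(met, sg)]
            decay = np.exp(-(te + t[None, :]) / t2s[(met, sg)])
            out += arr * decay
        out *= conc
        out *= np.exp(1j * 2 * np.pi * jitter_hz * t)[None, :]
        out *= eval_lineshape(t, pfl)[None, :]
        out *= pfl.phase_factors(t)
        return out

    def generate_sample(self, rng: np.random.Generator) -> JpressSample:
        cfg, grid = self.cfg, self.grid
        concs = self.prior.draw(self.metabolites, rng)
        t2s, delta1, water_delta1 = self._draw_t2s(rng)
        pfl = LineshapePFL.draw(grid.n_te, cfg, rng)
        water_pfl = LineshapePFL.draw(grid.n_te, cfg, rng)
        jitter = {m: float(rng.uniform(*cfg.shift_jitter_hz)) for m in self.metabolites}

        met_fids = {m: self._metabolite_fid(m, concs[m], t2s, pfl, jitter[m])
                    for m in self.metabolites}
        total_met_amp = sum(abs(f[0, 0]) for f in met_fids.values())
        if total_met_amp == 0:
            total_met_amp = 1e-6
        lo, hi = cfg.water_amp_ratio
        ratio = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        water_unit = self._metabolite_fid("water", 1.0, t2s, water_pfl, 0.0)
        unit_amp = abs(water_unit[0, 0])
        water_conc = ratio * total_met_amp / unit_amp if unit_amp > 0 else 0.0
        met_fids["water"] = water_conc * water_unit
        concs["water"] = water_conc

        n_comp = self.n_components
        comp_fids = np.zeros((n_comp, grid.n_te, grid.n_points), dtype=complex)
        comp_conc = np.zeros(n_comp)
        comp_t2 = np.zeros(n_comp)
        for i, (comp, mets) in enumerate(self.components):
            for m in mets:
                comp_fids[i] += met_fids[m]
                comp_conc[i] += concs[m]
            pairs = [(m, sg) for m in mets for sg in self.systems[m].subgroups]
            vals = np.array([t2s[p] for p in pairs])
            if cfg.t2_weighted_average:
                w = np.array([concs[m] * self.systems[m].subgroup_proton_count(sg)
                              for m, sg in pairs])
                comp_t2[i] = float(np.average(vals, weights=w)) if w.sum() > 0 \
                    else average_t2(vals)
            else:
                comp_t2[i] = average_t2(vals)

        clean = comp_fids.sum(axis=0)
        largest = max(abs(f[0, 0]) for m, f in met_fids.items() if m != "water")
        noisy, background = add_noise_and_artifacts(
            clean, rng, cfg, grid, reference_amplitude=max(largest, 1e-6))
        amplitudes = np.abs(comp_fids[:, :, 0]).T  # (n_te, n_comp)

        sample = JpressSample(
            input=noisy, component_fids=comp_fids, background=background,
            concentrations=comp_conc, avg_t2=comp_t2, amplitudes=amplitudes,
            component_names=list(self.component_names),
            meta={
                "delta1": delta1, "water_delta1": water_delta1,
                "subgroup_t2": {f"{m}/{sg}": v for (m, sg), v in t2s.items()},
                "pfl": pfl, "water_pfl": water_pfl,
                "metabolite_concs": concs, "water_ratio": ratio,
            },
        )
        resid = sample.input - (sample.component_fids.sum(axis=0) + sample.background)
        assert np.all(resid == 0), "conservation violated"
        if not (np.all(np.isfinite(comp_conc)) and np.all(comp_conc >= 0)
                and np.all(np.isfinite(comp_t2)) and np.all(comp_t2 >= 0)):
            raise AssertionError("non-finite or negative labels")
        return sample


def generate_dataset(gen: SampleGenerator, n: int, seed: int, path=None,
                     store_components: bool = False,
                     store_background: bool = False):
    """Generate ``n`` samples; stream to HDF5 if ``path`` given, else return
    them in memory as a dict of arrays."""
    if n < 1:
        raise ValueError("n must be >= 1")
    grid = gen.grid
    n_comp = gen.n_components
    if path is None:
        inputs = np.zeros((n, grid.n_te, grid.n_points, 2), dtype=np.float32)
        conc = np.zeros((n, n_comp), dtype=np.float32)
        t2 = np.zeros((n, n_comp), dtype=np.float32)
        amp = np.zeros((n, grid.n_te, n_comp), dtype=np.float32)
        comps = (np.zeros((n, n_comp, grid.n_te, grid.n_points, 2), dtype=np.float32)
                 if store_components else None)
        for i in range(n):
            s = gen.generate_sample(gen.rng_for(seed, i))
            inputs[i] = s.as_channels()
            conc[i] = s.concentrations
            t2[i] = s.avg_t2
            amp[i] = s.amplitudes
            if comps is not None:
                comps[i] = np.stack([s.component_fids.real, s.component_fids.imag], -1)
        out = {"input": inputs, "concentration": conc, "t2": t2, "amplitude": amp,
               "component_names": list(gen.component_names), "seed": seed}
        if comps is not None:
            out["components"] = comps
        return out
    with h5py.File(path, "w") as fh:
        fh.attrs["seed"] = seed
        fh.attrs["config_hash"] = gen.cfg.digest()
        fh.attrs["component_names"] = [c.encode() for c in gen.component_names]
        for k, v in grid.to_attrs().items():
            fh.attrs[k] = v
        d_in = fh.create_dataset("input", (n, grid.n_te, grid.n_points, 2), "f4")
        lab = fh.create_group("labels")
        d_c = lab.create_dataset("concentration", (n, n_comp), "f4")
        d_t = lab.create_dataset("t2", (n, n_comp), "f4")
        d_a = lab.create_dataset("amplitude", (n, grid.n_te, n_comp), "f4")
        d_comp = fh.create_dataset(
            "components", (n, n_comp, grid.n_te, grid.n_points, 2), "f4") \
            if store_components else None
        d_bg = fh.create_dataset(
            "background", (n, grid.n_te, grid.n_points, 2), "f4") \
            if store_background else None
        for i in range(n):
            s = gen.generate_sample(gen.rng_for(seed, i))
            d_in[i] = s.as_channels()
            d_c[i] = s.concentrations
            d_t[i] = s.avg_t2
            d_a[i] = s.amplitudes
            if d_comp is not None:
                d_comp[i] = np.stack([s.component_fids.real, s.component_fids.imag], -1)
            if d_bg is not None:
                d_bg[i] = np.stack([s.background.real, s.background.imag], -1)
    return path


def load_dataset(path) -> dict:
    """Load a generated HDF5 dataset into memory."""
    with h5py.File(path, "r") as fh:
        out = {
            "input": fh["input"][...],
            "concentration": fh["labels/concentration"][...],
            "t2": fh["labels/t2"][...],
            "amplitude": fh["labels/amplitude"][...],
            "component_names": [c.decode() if isinstance(c, bytes) else str(c)
                                for c in fh.attrs["component_names"]],
            "seed": int(fh.attrs["seed"]),
        }
        if "components" in fh:
            out["components"] = fh["components"][...]
        if "background" in fh:
            out["background"] = fh["background"][...]
    return out
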