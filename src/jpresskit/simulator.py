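"""Density-matrix simulation of J-coupled metabolite FIDs under an ideal
spin-echo PRESS acquisition.

For each echo time the full density matrix of every coupled subsystem is
evolved through 90x - TE/2 - 180y - TE/2 - acquire with ideal (instantaneous,
non-selective) pulses.  Chemical shift is refocused at the echo while scalar
coupling keeps evolving, producing the characteristic J modulation along the
TE dimension.  No relaxation or lineshape is applied here; those are
multiplicative factors applied downstream by the data generator.

Normalization: a subgroup's FID at TE=0 has first-point magnitude equal to
its number of protons at unit concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import h5py
from scipy.linalg import expm

from .spins import SpinSystem

__all__ = [
    "AcquisitionGrid",
    "BasisFid",
    "BasisSet",
    "build_hamiltonian",
    "simulate_press_fid",
    "simulate_basis",
]

MAX_SUBSYSTEM_SPINS = 8  # dense 2^n density matrices; 256-dim cap

_SX = np.array([[0, 0.5], [0.5, 0]], dtype=complex)
_SY = np.array([[0, -0.5j], [0.5j, 0]], dtype=complex)
_SZ = np.array([[0.5, 0], [0, -0.5]], dtype=complex)
_SP = np.array([[0, 1.0], [0, 0]], dtype=complex)  # I+ = Ix + i Iy


def default_te_values(n_te: int = 32, te_first: float = 0.035,
                      te_step: float = 0.010) -> np.ndarray:
    """Ascending TE grid: 35 ms first echo, uniform 10 ms increments."""
    return te_first + te_step * np.arange(n_te)


@dataclass
class AcquisitionGrid:
    """Sampling grid of the multi-echo acquisition.

    Defaults describe a typical 3 T JPRESS protocol: 32 echoes from 35 ms,
    2048 complex points at 2500 Hz spectral width, carrier on water.
    """

    n_te: int = 32
    te_values: np.ndarray = None  # type: ignore[assignment]
    n_points: int = 2048
    dwell_time: float = 4e-4          # s (spectral width 2500 Hz)
    spectrometer_freq: float = 123.2  # MHz (3 T proton)
    carrier_ppm: float = 4.7          # rotating-frame reference (water)

    def __post_init__(self) -> None:
        if self.te_values is None:
            self.te_values = default_te_values(self.n_te)
        self.te_values = np.asarray(self.te_values, dtype=float)
        if self.te_values.shape != (self.n_te,):
            raise ValueError("te_values length must equal n_te")
        if np.any(np.diff(self.te_values) <= 0):
            raise ValueError("te_values must be strictly ascending")
        if self.dwell_time <= 0:
            raise ValueError("dwell_time must be positive")

    @property
    def times(self) -> np.ndarray:
        """Acquisition time axis (s), starting at the echo top."""
        return np.arange(self.n_points) * self.dwell_time

    @property
    def spectral_width(self) -> float:
        return 1.0 / self.dwell_time

    def offset_hz(self, shift_ppm: float | np.ndarray) -> np.ndarray:
        """Rotating-frame offset (Hz) of a chemical shift."""
        return (np.asarray(shift_ppm) - self.carrier_ppm) * self.spectrometer_freq

    def to_attrs(self) -> dict:
        return {
            "n_te": self.n_te, "n_points": self.n_points,
            "dwell_time": self.dwell_time,
            "spectrometer_freq": self.spectrometer_freq,
            "carrier_ppm": self.carrier_ppm, "te_values": self.te_values,
        }

    @classmethod
    def from_attrs(cls, attrs) -> "AcquisitionGrid":
        return cls(n_te=int(attrs["n_te"]), te_values=np.array(attrs["te_values"]),
                   n_points=int(attrs["n_points"]), dwell_time=float(attrs["dwell_time"]),
                   spectrometer_freq=float(attrs["spectrometer_freq"]),
                   carrier_ppm=float(attrs["carrier_ppm"]))


@dataclass
class BasisFid:
    """Unit-concentration FID of one metabolite subgroup at one TE."""

    metabolite: str
    subgroup: str
    te: float
    samples: np.ndarray  # complex, length n_points
    dwell_time: float = 0.0  # s; acquisition time axis spacing

    @property
    def first_point(self) -> complex:
        return complex(self.samples[0])


def _embed(op: np.ndarray, pos: int, n: int) -> np.ndarray:
    """Single-spin operator embedded into the n-spin product space."""
    out = np.eye(1, dtype=complex)
    for k in range(n):
        out = np.kron(out, op if k == pos else np.eye(2, dtype=complex))
    return out


def _expand_subsystem(system: SpinSystem, groups: list[int]):
    """Expand equivalent protons of a coupled subsystem into single spins.

    A subsystem that is a single uncoupled group is kept as one spin whose
    polarization weight carries the proton count.
    """
    shifts: list[float] = []
    weights: list[float] = []
    members: list[int] = []  # group index per expanded spin
    if len(groups) == 1 and system.spins[groups[0]].n_equivalent > 1:
        g = groups[0]
        return [system.spins[g].shift], [float(system.spins[g].n_equivalent)], [g], np.zeros((1, 1))
    for g in groups:
        s = system.spins[g]
        for _ in range(s.n_equivalent):
            shifts.append(s.shift)
            weights.append(1.0)
            members.append(g)
    n = len(shifts)
    j = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            if members[a] != members[b]:
                j[a, b] = j[b, a] = system.j_matrix[members[a], members[b]]
    return shifts, weights, members, j


def _hamiltonian(shifts, j, grid: AcquisitionGrid) -> np.ndarray:
    """Strong-coupling rotating-frame Hamiltonian in rad/s."""
    n = len(shifts)
    dim = 2 ** n
    h = np.zeros((dim, dim), dtype=complex)
    sx = [_embed(_SX, i, n) for i in range(n)]
    sy = [_embed(_SY, i, n) for i in range(n)]
    sz = [_embed(_SZ, i, n) for i in range(n)]
    for i in range(n):
        h += 2 * np.pi * grid.offset_hz(shifts[i]) * sz[i]
    for i in range(n):
        for k in range(i + 1, n):
            if j[i, k] != 0:
                h += 2 * np.pi * j[i, k] * (sx[i] @ sx[k] + sy[i] @ sy[k] + sz[i] @ sz[k])
    return h


def build_hamiltonian(system: SpinSystem, grid: AcquisitionGrid) -> np.ndarray:
    """Rotating-frame Hamiltonian of a (small) fully expanded spin system.

    Raises a dimension error for systems whose expanded proton count exceeds
    the dense-evolution cap; larger metabolites are factored into coupled
    subsystems by :func:`simulate_press_fid`.
    """
    groups = list(range(len(system.spins)))
    shifts, _, _, j = _expand_subsystem(system, groups)
    if len(shifts) > MAX_SUBSYSTEM_SPINS:
        raise ValueError(
            f"{system.name}: {len(shifts)} expanded spins exceed the "
            f"{MAX_SUBSYSTEM_SPINS}-spin dense-evolution cap; factor into subsystems"
        )
    return _hamiltonian(shifts, j, grid)


class _SubsystemPropagator:
    """Pre-diagonalized evolution machinery for one coupled subsystem."""

    def __init__(self, system: SpinSystem, groups: list[int], grid: AcquisitionGrid):
        shifts, weights, members, j = _expand_subsystem(system, groups)
        if len(shifts) > MAX_SUBSYSTEM_SPINS:
            raise ValueError(
                f"{system.name} subsystem {groups}: {len(shifts)} spins exceed "
                f"the {MAX_SUBSYSTEM_SPINS}-spin cap"
            )
        self.subgroup = system.spins[groups[0]].subgroup
        n = len(shifts)
        h = _hamiltonian(shifts, j, grid)
        self.evals, self.evecs = np.linalg.eigh(h)
        v = self.evecs
        sum_x = sum(_embed(_SX, i, n) for i in range(n))
        sum_y = sum(_embed(_SY, i, n) for i in range(n))
        rho0 = sum(w * _embed(_SZ, i, n) for i, w in enumerate(weights))
        r90 = expm(-1j * (np.pi / 2) * sum_x)
        self.r180_eig = v.conj().T @ expm(-1j * np.pi * sum_y) @ v
        self.rho1_eig = v.conj().T @ (r90 @ rho0 @ r90.conj().T) @ v
        det = sum(_embed(_SP, i, n) for i in range(n))
        self.det_eig = v.conj().T @ det @ v
        # identity traces of spectator spins inflate Tr(det rho) by 2^(n-1)
        self.scale = 2.0 / 2 ** (n - 1)

    def lines(self, te: float):
        """(amplitudes, frequencies rad/s) of the FID at echo time ``te``."""
        phase = np.exp(-1j * self.evals * (te / 2.0))
        half = phase[:, None] * self.rho1_eig * phase.conj()[None, :]
        rho = self.r180_eig @ half @ self.r180_eig.conj().T
        rho = phase[:, None] * rho * phase.conj()[None, :]
        # s(t) = Tr(det rho(t)) = sum_ab det_ab rho_ba exp(-i (w_b - w_a) t)
        amp = 1.0j * self.scale * self.det_eig * rho.T  # receiver: TE=0 singlet -> +1
        omega = self.evals[None, :] - self.evals[:, None]
        keep = np.abs(amp) > 1e-10
        return amp[keep], -omega[keep]


def _propagators(system: SpinSystem, grid: AcquisitionGrid) -> list[_SubsystemPropagator]:
    return [_SubsystemPropagator(system, groups, grid)
            for groups in system.subsystems()]


def simulate_press_fid(system: SpinSystem, te: float,
                       grid: AcquisitionGrid) -> list[BasisFid]:
    """Simulate the ideal-pulse spin-echo FID of one metabolite at one TE.

    Returns one :class:`BasisFid` per subgroup; no relaxation or lineshape
    is applied.
    """
    if te < 0:
        raise ValueError("te must be non-negative")
    t = grid.times
    per_subgroup: dict[str, np.ndarray] = {}
    for prop in _propagators(system, grid):
        amp, omega = prop.lines(te)
        fid = amp @ np.exp(1j * np.outer(omega, t))
        key = prop.subgroup
        per_subgroup[key] = per_subgroup.get(key, 0) + fid
    return [BasisFid(system.name, sg, te, samples, grid.dwell_time)
            for sg, samples in per_subgroup.items()]


@dataclass
class BasisSet:
    """Unit-concentration basis FIDs keyed (metabolite, subgroup)."""

    grid: AcquisitionGrid
    fids: dict[tuple[str, str], np.ndarray]      # (n_te, n_points) complex
    protons: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def metabolites(self) -> list[str]:
        seen: list[str] = []
        for met, _ in self.fids:
            if met not in seen:
                seen.append(met)
        return seen

    def subgroups_of(self, metabolite: str) -> list[str]:
        return [sg for met, sg in self.fids if met == metabolite]

    def get(self, metabolite: str, subgroup: str, te_index: int) -> np.ndarray:
        try:
            return self.fids[(metabolite, subgroup)][te_index]
        except KeyError:
            raise KeyError(
                f"no basis entry for metabolite={metabolite!r} subgroup={subgroup!r}"
            ) from None

    def save(self, path) -> None:
        """Cache to HDF5: groups /basis/<metabolite>/<subgroup>, complex as
        a trailing dimension of size 2; grid metadata in root attributes."""
        with h5py.File(path, "w") as fh:
            for k, v in self.grid.to_attrs().items():
                fh.attrs[k] = v
            root = fh.create_group("basis")
            for (met, sg), arr in self.fids.items():
                g = root.require_group(met).create_group(sg)
                g.create_dataset("fid", data=np.stack([arr.real, arr.imag], axis=-1))
                g.attrs["protons"] = self.protons.get((met, sg), 0)

    @classmethod
    def load(cls, path) -> "BasisSet":
        with h5py.File(path, "r") as fh:
            grid = AcquisitionGrid.from_attrs(fh.attrs)
            fids, protons = {}, {}
            for met, mg in fh["basis"].items():
                for sg, g in mg.items():
                    raw = g["fid"][...]
                    fids[(met, sg)] = raw[..., 0] + 1j * raw[..., 1]
                    protons[(met, sg)] = int(g.attrs["protons"])
        return cls(grid, fids, protons)


def simulate_basis(systems: list[SpinSystem], grid: AcquisitionGrid,
                   cache_path=None) -> BasisSet:
    """Simulate the complete unit-concentration basis over all TEs.

    Deterministic given inputs; optionally cached to HDF5.  The per-TE loop
    reuses one diagonalization per coupled subsystem, synthesizing every FID
    from its coherence line list.
    """
    names = [s.name for s in systems]
    if len(set(names)) != len(names):
        raise ValueError("duplicate metabolite names in basis request")
    t = grid.times
    fids: dict[tuple[str, str], np.ndarray] = {}
    protons: dict[tuple[str, str], int] = {}
    for system in systems:
        for prop in _propagators(system, grid):
            key = (system.name, prop.subgroup)
            acc = fids.setdefault(
                key, np.zeros((grid.n_te, grid.n_points), dtype=complex))
            for k, te in enumerate(grid.te_values):
                amp, omega = prop.lines(te)
                acc[k] += amp @ np.exp(1j * np.outer(omega, t))
        for sg in system.subgroups:
            protons[(system.name, sg)] = system.subgroup_proton_count(sg)
    basis = BasisSet(grid, fids, protons)
    if cache_path is not None:
        basis.save(cache_path)
    return basis
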