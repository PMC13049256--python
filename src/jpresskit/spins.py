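"""Spin-system definitions for the brain metabolites observed by JPRESS.

A :class:`SpinSystem` lists proton groups (chemical shift, multiplicity,
subgroup label) and the scalar-coupling matrix between the groups.  Subgroups
are maximal sets of mutually coupled protons sharing a moiety label; they are
the unit that carries an individual T2 in the generative model.  Chemical
shifts and J couplings follow the standard published proton tables for brain
metabolites at physiological pH; weakly contributing moieties (exchangeable
protons, the glycerol backbone of GPCho) are omitted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Spin", "SpinSystem", "builtin_systems", "load_systems", "dump_systems"]


@dataclass(frozen=True)
class Spin:
    """One group of equivalent protons."""

    shift: float            # chemical shift, ppm
    subgroup: str           # moiety label; protons sharing it share one T2
    n_equivalent: int = 1   # number of magnetically equivalent protons


@dataclass
class SpinSystem:
    """A metabolite: proton groups plus the J-coupling matrix between groups.

    ``j_matrix[i, j]`` is the scalar coupling (Hz) between every proton of
    group ``i`` and every proton of group ``j``; couplings within a group of
    equivalent protons do not affect the spectrum and are taken as zero.
    """

    name: str
    spins: list[Spin]
    j_matrix: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.spins)
        if self.j_matrix is None:
            self.j_matrix = np.zeros((n, n))
        self.j_matrix = np.asarray(self.j_matrix, dtype=float)
        if self.j_matrix.shape != (n, n):
            raise ValueError(
                f"{self.name}: j_matrix shape {self.j_matrix.shape} != ({n}, {n})"
            )
        if not np.allclose(self.j_matrix, self.j_matrix.T):
            raise ValueError(f"{self.name}: j_matrix must be symmetric")
        if np.any(np.diag(self.j_matrix) != 0):
            raise ValueError(f"{self.name}: j_matrix diagonal must be zero")
        for s in self.spins:
            if not s.subgroup:
                raise ValueError(f"{self.name}: every spin needs a subgroup label")

    @property
    def proton_count(self) -> int:
        return sum(s.n_equivalent for s in self.spins)

    @property
    def subgroups(self) -> list[str]:
        """Subgroup labels in order of first appearance."""
        seen: list[str] = []
        for s in self.spins:
            if s.subgroup not in seen:
                seen.append(s.subgroup)
        return seen

    def subgroup_proton_count(self, subgroup: str) -> int:
        return sum(s.n_equivalent for s in self.spins if s.subgroup == subgroup)

    def subsystems(self, min_coupling: float = 0.5) -> list[list[int]]:
        """Indices of spin groups forming independent coupled subsystems.

        Groups with no coupling path between them evolve independently and
        are factored apart before density-matrix evolution; couplings below
        ``min_coupling`` Hz are dropped when building the coupling graph.
        """
        n = len(self.spins)
        adj = np.abs(self.j_matrix) >= min_coupling
        seen = np.zeros(n, dtype=bool)
        comps: list[list[int]] = []
        for i in range(n):
            if seen[i]:
                continue
            stack, comp = [i], []
            seen[i] = True
            while stack:
                k = stack.pop()
                comp.append(k)
                for j in np.nonzero(adj[k])[0]:
                    if not seen[j]:
                        seen[j] = True
                        stack.append(int(j))
            comps.append(sorted(comp))
        return comps


def _sys(name: str, groups, j_pairs=()) -> SpinSystem:
    spins = [Spin(shift, sub, n) for shift, sub, n in groups]
    n = len(spins)
    j = np.zeros((n, n))
    for a, b, val in j_pairs:
        j[a, b] = j[b, a] = val
    return SpinSystem(name, spins, j)


def builtin_systems() -> dict[str, SpinSystem]:
    """The 14 target metabolites plus water."""
    systems = [
        _sys("NAA",
             [(2.008, "acetyl", 3),
              (4.382, "aspartyl", 1), (2.673, "aspartyl", 1), (2.486, "aspartyl", 1)],
             [(1, 2, 3.86), (1, 3, 9.82), (2, 3, -15.59)]),
        _sys("NAAG",
             [(2.042, "acetyl", 3),
              (4.607, "aspartyl", 1), (2.721, "aspartyl", 1), (2.519, "aspartyl", 1),
              (4.128, "glutamyl", 1), (1.881, "glutamyl", 1), (2.049, "glutamyl", 1),
              (2.180, "glutamyl", 1), (2.190, "glutamyl", 1)],
             [(1, 2, 4.41), (1, 3, 9.52), (2, 3, -15.91),
              (4, 5, 4.61), (4, 6, 8.42), (5, 6, -14.28),
              (5, 7, 10.56), (5, 8, 6.09), (6, 7, 4.90), (6, 8, 11.11),
              (7, 8, -15.28)]),
        _sys("Cr", [(3.027, "methyl", 3), (3.913, "methylene", 2)]),
        _sys("PCr", [(3.029, "methyl", 3), (3.930, "methylene", 2)]),
        _sys("PCho",
             [(3.209, "trimethyl", 9), (4.282, "ethylene", 2), (3.641, "ethylene", 2)],
             [(1, 2, 6.0)]),
        _sys("GPCho",
             [(3.212, "trimethyl", 9), (4.312, "ethylene", 2), (3.659, "ethylene", 2)],
             [(1, 2, 6.0)]),
        _sys("Glu",
             [(3.746, "backbone", 1), (2.042, "backbone", 1), (2.120, "backbone", 1),
              (2.336, "backbone", 1), (2.352, "backbone", 1)],
             [(0, 1, 7.33), (0, 2, 4.65), (1, 2, -14.85),
              (1, 3, 6.43), (1, 4, 8.39), (2, 3, 8.48), (2, 4, 6.88),
              (3, 4, -15.92)]),
        _sys("Gln",
             [(3.753, "backbone", 1), (2.129, "backbone", 1), (2.109, "backbone", 1),
              (2.432, "backbone", 1), (2.454, "backbone", 1)],
             [(0, 1, 5.84), (0, 2, 6.53), (1, 2, -14.45),
              (1, 3, 9.16), (1, 4, 6.35), (2, 3, 6.88), (2, 4, 9.25),
              (3, 4, -15.55)]),
        _sys("GSH",
             [(3.769, "glycinyl", 2),
              (4.561, "cysteinyl", 1), (2.926, "cysteinyl", 1), (2.975, "cysteinyl", 1),
              (3.769, "glutamyl", 1), (2.159, "glutamyl", 1), (2.146, "glutamyl", 1),
              (2.510, "glutamyl", 1), (2.560, "glutamyl", 1)],
             [(1, 2, 7.09), (1, 3, 4.71), (2, 3, -14.06),
              (4, 5, 6.34), (4, 6, 6.36), (5, 6, -15.48),
              (5, 7, 6.70), (5, 8, 7.60), (6, 7, 7.60), (6, 8, 6.70),
              (7, 8, -15.92)]),
        _sys("Tau",
             [(3.420, "chain", 2), (3.246, "chain", 2)],
             [(0, 1, 6.70)]),
        _sys("Asp",
             [(3.891, "backbone", 1), (2.801, "backbone", 1), (2.653, "backbone", 1)],
             [(0, 1, 3.65), (0, 2, 9.11), (1, 2, -17.43)]),
        _sys("mI",
             [(3.522, "ring", 1), (4.054, "ring", 1), (3.522, "ring", 1),
              (3.614, "ring", 1), (3.269, "ring", 1), (3.614, "ring", 1)],
             [(0, 1, 2.89), (1, 2, 3.01), (2, 3, 9.99),
              (3, 4, 9.48), (4, 5, 9.48), (5, 0, 9.99)]),
        _sys("GABA",
             [(2.284, "chain", 2), (1.889, "chain", 2), (3.013, "chain", 2)],
             [(0, 1, 7.30), (1, 2, 7.40)]),
        _sys("Lac",
             [(4.097, "backbone", 1), (1.313, "backbone", 3)],
             [(0, 1, 6.93)]),
        _sys("water", [(4.70, "water", 2)]),
    ]
    return {s.name: s for s in systems}


def dump_systems(systems: dict[str, SpinSystem], path) -> None:
    """Write spin systems to a JSON file (name, shifts, subgroups, J pairs)."""
    out = {}
    for name, sys_ in systems.items():
        pairs = [
            [i, j, float(sys_.j_matrix[i, j])]
            for i in range(len(sys_.spins))
            for j in range(i + 1, len(sys_.spins))
            if sys_.j_matrix[i, j] != 0
        ]
        out[name] = {
            "spins": [[s.shift, s.subgroup, s.n_equivalent] for s in sys_.spins],
            "j_pairs": pairs,
        }
    with open(path, "w") as fh:
        json.dump(out, fh, indent=1)


def load_systems(path) -> dict[str, SpinSystem]:
    """Read spin systems from the JSON schema written by :func:`dump_systems`."""
    with open(path) as fh:
        raw = json.load(fh)
    return {
        name: _sys(name,
                   [(s[0], s[1], int(s[2])) for s in entry["spins"]],
                   [(int(a), int(b), v) for a, b, v in entry["j_pairs"]])
        for name, entry in raw.items()
    }
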