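"""Multi-model PDB coordinate handling and EF-lobe residue-range definitions.

A "structure ensemble" is an ordered list of models sharing one atom roster:
each model is one NMR model or one trajectory frame exported as a
MODEL/ENDMDL block.  All downstream geometry is Cα-based, but models retain
every atom read so that ensembles can be round-tripped.

The calmodulin lobe registry holds default helix residue ranges for the four
EF-hands of vertebrate calmodulin (148 residues).  The exact helix
boundaries used in published analyses vary by a residue or two; the defaults
here are canonical α-helix assignments and can be overridden from a flat
key-value config file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "Model",
    "StructureEnsemble",
    "ResidueRange",
    "EFHandDef",
    "EFLobeDef",
    "read_structure_models",
    "write_structure_models",
    "select_ca",
    "calmodulin_lobe_registry",
    "load_helix_config",
]


@dataclass(frozen=True)
class ResidueRange:
    """Inclusive 1-based residue range on one chain (author numbering)."""

    chain: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"ResidueRange start {self.start} > end {self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def residues(self) -> range:
        return range(self.start, self.end + 1)


@dataclass(frozen=True)
class EFHandDef:
    """One EF-hand: entering helix E, Ca-binding loop, exiting helix F."""

    name: str
    helixE: ResidueRange
    loop: ResidueRange
    helixF: ResidueRange

    def __post_init__(self) -> None:
        segs = [self.helixE, self.loop, self.helixF]
        for a, b in zip(segs, segs[1:]):
            if a.end >= b.start:
                raise ValueError(
                    f"{self.name}: segments must be non-overlapping and in "
                    f"sequence order (got {a} before {b})"
                )
        for h in (self.helixE, self.helixF):
            if len(h) < 5:
                raise ValueError(f"{self.name}: helix {h} shorter than 5 residues")

    def segments(self) -> tuple[ResidueRange, ResidueRange, ResidueRange]:
        return (self.helixE, self.loop, self.helixF)


@dataclass(frozen=True)
class EFLobeDef:
    """A pair of EF-hands related by an approximate two-fold axis."""

    name: str
    hand1: EFHandDef
    hand2: EFHandDef

    def __post_init__(self) -> None:
        if self.hand1.helixF.end >= self.hand2.helixE.start:
            raise ValueError(
                f"{self.name}: hand1 must precede hand2 in sequence"
            )


#: atom identity key: (chain, residue number, atom name)
AtomKey = tuple[str, int, str]


@dataclass
class Model:
    """One coordinate set: parallel arrays of atom identities and positions."""

    model_index: int
    chains: list[str]
    resnums: list[int]
    resnames: list[str]
    atomnames: list[str]
    altlocs: list[str]
    coords: np.ndarray  # (n_atoms, 3) Å

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"model {self.model_index}: non-finite coordinates")

    def __len__(self) -> int:
        return len(self.resnums)

    def atom_keys(self) -> list[AtomKey]:
        return list(zip(self.chains, self.resnums, self.atomnames))

    def _ca_rows(self) -> dict[tuple[str, int], int]:
        """First-CA row index per (chain, residue), built once per model."""
        cache = getattr(self, "_ca_cache", None)
        if cache is None:
            cache = {}
            for row, (ch, num, aname) in enumerate(
                zip(self.chains, self.resnums, self.atomnames)
            ):
                if aname == "CA":
                    cache.setdefault((ch, num), row)
            object.__setattr__(self, "_ca_cache", cache)
        return cache

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Model":
        """Copy with coordinates mapped through x -> R x + t."""
        return Model(
            self.model_index,
            list(self.chains),
            list(self.resnums),
            list(self.resnames),
            list(self.atomnames),
            list(self.altlocs),
            self.coords @ np.asarray(rotation, dtype=float).T
            + np.asarray(translation, dtype=float),
        )


@dataclass
class StructureEnsemble:
    models: list[Model]
    source_id: str = ""

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("ensemble must contain at least one model")
        ref = self.models[0].atom_keys()
        for m in self.models[1:]:
            keys = m.atom_keys()
            if keys != ref:
                missing = sorted(set(ref) - set(keys))
                extra = sorted(set(keys) - set(ref))
                raise ValueError(
                    f"model {m.model_index} atom roster differs from model "
                    f"{self.models[0].model_index}: "
                    f"missing {missing[:5]}{'...' if len(missing) > 5 else ''}, "
                    f"extra {extra[:5]}{'...' if len(extra) > 5 else ''}"
                )

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models)


def _model_from_gemmi(gm: gemmi.Model, index: int, altloc_policy: str) -> Model:
    chains: list[str] = []
    resnums: list[int] = []
    resnames: list[str] = []
    atomnames: list[str] = []
    altlocs: list[str] = []
    xyz: list[tuple[float, float, float]] = []
    for chain in gm:
        for res in chain:
            if res.seqid.icode not in ("", " "):
                raise ValueError(
                    f"insertion code {res.seqid.icode!r} at "
                    f"{chain.name}:{res.seqid.num} is not supported"
                )
            seen: set[str] = set()
            for atom in res:
                alt = atom.altloc
                alt = "" if alt in ("", " ", "\0") else alt
                if altloc_policy == "first":
                    if atom.name in seen:
                        continue
                elif alt not in ("", "A"):
                    continue
                elif atom.name in seen:
                    continue
                seen.add(atom.name)
                chains.append(chain.name)
                resnums.append(res.seqid.num)
                resnames.append(res.name)
                atomnames.append(atom.name)
                altlocs.append(alt)
                xyz.append((atom.pos.x, atom.pos.y, atom.pos.z))
    if not xyz:
        raise ValueError(f"model {index} contains no atoms")
    return Model(index, chains, resnums, resnames, atomnames, altlocs,
                 np.array(xyz, dtype=float))


def read_structure_models(path: str | Path, altloc_policy: str = "A") -> StructureEnsemble:
    """Read a (possibly multi-model) PDB file into an ensemble.

    Files without MODEL records yield a single model.  Under the default
    altloc policy only blank or 'A' alternate locations are kept, one atom
    per (residue, atom-name); ``altloc_policy="first"`` keeps the first
    altloc encountered instead.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if altloc_policy not in ("A", "first"):
        raise ValueError(f"unknown altloc policy {altloc_policy!r}")
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no models found")
    models = [
        _model_from_gemmi(gm, i + 1, altloc_policy) for i, gm in enumerate(st)
    ]
    return StructureEnsemble(models, source_id=path.stem)


def write_structure_models(ensemble: StructureEnsemble, path: str | Path) -> None:
    """Write an ensemble as a multi-model PDB (MODEL/ENDMDL blocks).

    Round-trips coordinates to the PDB field precision of 1e-3 Å.
    """
    st = gemmi.Structure()
    st.name = ensemble.source_id or "hvmap"
    for m in ensemble.models:
        gm = gemmi.Model(m.model_index)
        cur_chain: gemmi.Chain | None = None
        cur_res: gemmi.Residue | None = None
        for ch, num, rname, aname, alt, pos in zip(
            m.chains, m.resnums, m.resnames, m.atomnames, m.altlocs, m.coords
        ):
            if cur_chain is None or cur_chain.name != ch:
                cur_chain = gemmi.Chain(ch)
                gm.add_chain(cur_chain)
                cur_chain = gm[-1]
                cur_res = None
            if cur_res is None or cur_res.seqid.num != num:
                res = gemmi.Residue()
                res.name = rname
                res.seqid = gemmi.SeqId(num, " ")
                cur_chain.add_residue(res)
                cur_res = cur_chain[-1]
            atom = gemmi.Atom()
            atom.name = aname
            atom.altloc = alt or "\0"
            atom.element = gemmi.Element(aname[:1] if aname[:1].isalpha() else "C")
            atom.pos = gemmi.Position(*pos)
            cur_res.add_atom(atom)
        st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


def select_ca(model: Model, rng: ResidueRange) -> np.ndarray:
    """Cα coordinates for every residue in ``rng``, in residue order.

    Exactly one coordinate per residue (first matching CA under the loaded
    altloc policy).  Raises if any residue in the range lacks a CA atom.
    """
    rows = model._ca_rows()
    idx = [rows.get((rng.chain, r)) for r in rng.residues()]
    missing = [r for r, i in zip(rng.residues(), idx) if i is None]
    if missing:
        raise ValueError(
            f"residues lacking a CA atom in {rng.chain}:{rng.start}-{rng.end}: "
            f"{missing}"
        )
    return model.coords[idx]


# ---------------------------------------------------------------------------
# Calmodulin registry

_DEFAULT_HELICES: dict[str, tuple[int, int]] = {
    "E1": (6, 19),
    "F1": (29, 38),
    "E2": (45, 55),
    "F2": (65, 75),
    "E3": (82, 92),
    "F3": (102, 111),
    "E4": (118, 128),
    "F4": (138, 146),
}


def _hand(name: str, e: tuple[int, int], f: tuple[int, int], chain: str) -> EFHandDef:
    loop = ResidueRange(chain, e[1] + 1, f[0] - 1)
    return EFHandDef(
        name,
        helixE=ResidueRange(chain, *e),
        loop=loop,
        helixF=ResidueRange(chain, *f),
    )


def calmodulin_lobe_registry(
    config_path: str | Path | None = None, chain: str = "A"
) -> tuple[EFLobeDef, EFLobeDef]:
    """Default EF-lobe definitions for vertebrate calmodulin (148 residues).

    Returns ``(N_lobe, C_lobe)``: the N-lobe pairs EF1 (helices E1/F1) with
    EF2 (E2/F2); the C-lobe pairs EF3 with EF4.  Helix boundaries are
    canonical α-helix assignments (approximate to ±2 residues per terminus)
    and may be overridden via ``config_path``, a flat key-value file mapping
    helix names to ``chain:start-end``::

        E1 = A:5-20
        F1 = A:29-38
    """
    helices = dict(_DEFAULT_HELICES)
    chains = {name: chain for name in helices}
    if config_path is not None:
        for name, (ch, lo, hi) in load_helix_config(config_path).items():
            if name not in helices:
                raise ValueError(f"unknown helix name {name!r} in {config_path}")
            helices[name] = (lo, hi)
            chains[name] = ch
    def hand(name: str, e: str, f: str) -> EFHandDef:
        return _hand(name, helices[e], helices[f], chains[e])
    n_lobe = EFLobeDef("N-lobe", hand("EF1", "E1", "F1"), hand("EF2", "E2", "F2"))
    c_lobe = EFLobeDef("C-lobe", hand("EF3", "E3", "F3"), hand("EF4", "E4", "F4"))
    return n_lobe, c_lobe


def load_helix_config(path: str | Path) -> dict[str, tuple[str, int, int]]:
    """Parse ``NAME = chain:start-end`` lines; '#' starts a comment."""
    out: dict[str, tuple[str, int, int]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            name, spec = (s.strip() for s in line.split("=", 1))
            ch, rng = (s.strip() for s in spec.split(":", 1))
            lo, hi = (int(s) for s in rng.split("-", 1))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: cannot parse {raw!r}") from exc
        out[name] = (ch, lo, hi)
    return out
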