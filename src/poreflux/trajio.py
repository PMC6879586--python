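"""Trajectory/structure I/O, role annotation, and tidy tables.

Reads PDB/GRO structures and XTC/TRR/DCD trajectories through MDAnalysis,
converting everything to internal units (nm, ns) on the way in.  Role
annotation maps structural roles (selectivity-filter oxygens, gate CA atoms,
ion and water species) onto atom indices per subunit, either from explicit
selections or by TVGYG motif search.
"""

from __future__ import annotations

import configparser
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AnnotationError, FormatError, SchemaError
from .units import ANGSTROM_TO_NM, PS_TO_NS

__all__ = [
    "ReplicaMeta",
    "Replica",
    "TrajectoryEnsemble",
    "ChannelAnnotation",
    "RestraintScheme",
    "SF_ROLES",
    "GATE_ROLES",
    "DEFAULT_ROLE_CONFIG",
    "load_ensemble",
    "build_annotation",
    "make_restraint_series",
    "write_tidy",
    "read_tidy",
    "write_ensemble",
]

#: Oxygen-plane roles, ordered from the cavity side upward.  Consecutive
#: planes bound the ion binding sites S4 (bottom) … S0 (top).
SF_ROLES = ("T_OG1", "T_O", "V_O", "G1_O", "Y_O", "G2_O")

#: Additional per-subunit filter roles (threonine CA, valine carbonyl C).
SF_EXTRA_ROLES = ("T_CA", "V_C", "T59_CG")

GATE_ROLES = ("P19", "F97", "A88", "I84_tip")

_AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "HSD": "H", "HSE": "H", "HSP": "H",
}

#: Role configuration matching the synthetic generator's atom naming.
DEFAULT_ROLE_CONFIG: dict[str, dict[str, str]] = {
    "sf": {"motif": "TVGYG"},
    "gate": {
        "P19": "resname PRO and name CA",
        "F97": "resname PHE and name CA",
        "A88": "resname ALA and name CA",
        "I84_tip": "resname ILE and name CD",
    },
    "species": {
        "ion": "name K and resname K",
        "water_oxygen": "resname SOL and name OW",
    },
}


@dataclass
class ReplicaMeta:
    forcefield: str = "synthetic"
    voltage_mv: float = 0.0
    restraint: str = ""
    seed: int | None = None


@dataclass
class Replica:
    coords: np.ndarray  # (frames, atoms, 3) nm
    box: np.ndarray  # (frames, 3) nm
    times: np.ndarray  # (frames,) ns, strictly increasing
    meta: ReplicaMeta = field(default_factory=ReplicaMeta)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise FormatError("coords must have shape (frames, atoms, 3)")
        n = self.coords.shape[0]
        if self.box.shape != (n, 3):
            raise FormatError("box must have shape (frames, 3)")
        if self.times.shape != (n,):
            raise FormatError("times must have one entry per frame")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise FormatError("times must be strictly increasing")
        if not np.all(self.box > 0):
            raise FormatError("box lengths must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def duration(self) -> float:
        """Sampled time span in ns (last minus first frame time)."""
        return float(self.times[-1] - self.times[0])


@dataclass
class TrajectoryEnsemble:
    replicas: list[Replica]

    def __post_init__(self) -> None:
        if not self.replicas:
            raise FormatError("ensemble needs at least one replica")
        n_atoms = {r.n_atoms for r in self.replicas}
        if len(n_atoms) != 1:
            raise FormatError(f"replicas disagree on atom count: {sorted(n_atoms)}")

    @property
    def n_replicas(self) -> int:
        return len(self.replicas)

    @property
    def n_atoms(self) -> int:
        return self.replicas[0].n_atoms

    @property
    def total_time(self) -> float:
        return float(sum(r.duration for r in self.replicas))


@dataclass
class ChannelAnnotation:
    """Per-subunit role → atom-index map.

    ``sf`` holds one atom index per subunit for every selectivity-filter
    role; ``gate`` holds gate-region roles and may be empty for topologies
    where only the filter is analysed.
    """

    n_subunits: int
    sf: dict[str, tuple[int, ...]]
    gate: dict[str, tuple[int, ...]] = field(default_factory=dict)
    ion_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    water_oxygen_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        if self.n_subunits not in (2, 4):
            raise AnnotationError("n_subunits must be 2 or 4")
        for role in SF_ROLES:
            if role not in self.sf:
                raise AnnotationError(f"missing SF role {role!r}")
        for role, idx in {**self.sf, **self.gate}.items():
            if len(idx) != self.n_subunits:
                raise AnnotationError(
                    f"role {role!r} annotated in {len(idx)} of {self.n_subunits} subunits"
                )
        self.ion_indices = np.asarray(self.ion_indices, dtype=int)
        self.water_oxygen_indices = np.asarray(self.water_oxygen_indices, dtype=int)
        protein = {i for idx in {**self.sf, **self.gate}.values() for i in idx}
        ions = set(self.ion_indices.tolist())
        waters = set(self.water_oxygen_indices.tolist())
        if (protein & ions) or (protein & waters) or (ions & waters):
            raise AnnotationError("ion, water, and protein index sets must be disjoint")

    def role_indices(self, role: str) -> np.ndarray:
        if role in self.sf:
            return np.asarray(self.sf[role], dtype=int)
        if role in self.gate:
            return np.asarray(self.gate[role], dtype=int)
        raise AnnotationError(f"role {role!r} is not annotated")


@dataclass(frozen=True)
class RestraintScheme:
    """One row of a restrained-distance scheme table (all distances in nm)."""

    name: str
    d_p19_opposite: float
    d_p19_adjacent: float
    d_f97_opposite: float
    d_f97_adjacent: float
    k: float = 1000.0

    def __post_init__(self) -> None:
        d = (self.d_p19_opposite, self.d_p19_adjacent, self.d_f97_opposite, self.d_f97_adjacent)
        if any(x <= 0 for x in d):
            raise ValueError("restraint distances must be positive")
        if self.d_p19_opposite < self.d_p19_adjacent or self.d_f97_opposite < self.d_f97_adjacent:
            raise ValueError("opposite distances must be >= adjacent distances")

    def distances(self) -> tuple[float, float, float, float]:
        return (self.d_p19_opposite, self.d_p19_adjacent, self.d_f97_opposite, self.d_f97_adjacent)


def make_restraint_series(base: RestraintScheme, offsets: Iterable[float]) -> list[RestraintScheme]:
    """Shift all four restrained distances of ``base`` by each offset (nm)."""
    out = []
    for off in offsets:
        if not np.isfinite(off):
            raise ValueError("offsets must be finite")
        sign = "+" if off >= 0 else "−"
        name = base.name if off == 0 else f"{base.name} {sign} {abs(off):g}"
        try:
            out.append(
                replace(
                    base,
                    name=name,
                    d_p19_opposite=base.d_p19_opposite + off,
                    d_p19_adjacent=base.d_p19_adjacent + off,
                    d_f97_opposite=base.d_f97_opposite + off,
                    d_f97_adjacent=base.d_f97_adjacent + off,
                )
            )
        except ValueError as exc:
            raise ValueError(f"offset {off} makes a distance non-positive") from exc
    return out


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------


def _import_mda():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import MDAnalysis as mda
    return mda


def load_ensemble(
    structure_path: str | Path,
    trajectory_paths: Sequence[str | Path] | None = None,
    annotation_config: Mapping | str | Path | None = None,
    metas: Sequence[ReplicaMeta] | None = None,
    dt_ns: float | None = None,
) -> tuple[TrajectoryEnsemble, ChannelAnnotation | None]:
    """Load one replica per trajectory file onto a shared topology.

    Coordinates are converted to nm and times to ns regardless of the source
    format's native units.  When the source provides no usable time axis
    (static structures, some DCDs), frame times fall back to ``dt_ns`` times
    the frame index (default 1 ns/frame).
    """
    mda = _import_mda()
    structure_path = Path(structure_path)
    if not structure_path.exists():
        raise FormatError(f"structure file not found: {structure_path}")

    traj_list = [Path(p) for p in (trajectory_paths or [])]
    for p in traj_list:
        if not p.exists():
            raise FormatError(f"trajectory file not found: {p}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ref = mda.Universe(str(structure_path))
    n_atoms = ref.atoms.n_atoms

    replicas: list[Replica] = []
    sources = traj_list if traj_list else [None]
    for i, traj in enumerate(sources):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                u = mda.Universe(str(structure_path), str(traj)) if traj else ref
        except Exception as exc:  # MDAnalysis raises assorted types here
            raise FormatError(f"cannot read trajectory {traj}: {exc}") from exc
        if u.atoms.n_atoms != n_atoms:
            raise FormatError(
                f"atom count mismatch: structure has {n_atoms}, {traj} has {u.atoms.n_atoms}"
            )
        coords, boxes, times = [], [], []
        for ts in u.trajectory:
            coords.append(ts.positions * ANGSTROM_TO_NM)
            if ts.dimensions is None or not np.all(ts.dimensions[:3] > 0):
                boxes.append(np.full(3, np.nan))
            else:
                boxes.append(ts.dimensions[:3] * ANGSTROM_TO_NM)
            times.append(ts.time * PS_TO_NS)
        coords = np.asarray(coords)
        boxes = np.asarray(boxes)
        times = np.asarray(times)
        if np.any(np.isnan(boxes)):
            boxes = np.where(np.isnan(boxes), 100.0, boxes)  # effectively non-periodic
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            step = dt_ns if dt_ns is not None else 1.0
            times = np.arange(len(times), dtype=float) * step
        meta = metas[i] if metas is not None else ReplicaMeta()
        replicas.append(Replica(coords=coords, box=boxes, times=times, meta=meta))

    annotation = None
    if annotation_config is not None:
        annotation = build_annotation(ref, annotation_config)
    return TrajectoryEnsemble(replicas=replicas), annotation


def _parse_role_config(config: Mapping | str | Path) -> dict[str, dict[str, str]]:
    if isinstance(config, (str, Path)):
        parser = configparser.ConfigParser()
        parser.optionxform = str  # keep role-name case
        read = parser.read(str(config))
        if not read:
            raise AnnotationError(f"cannot read role config {config}")
        return {s: dict(parser[s]) for s in parser.sections()}
    return {k: dict(v) for k, v in config.items()}


def _chain_groups(u) -> list:
    """Atom groups per chain, preferring segments, then chainIDs."""
    if len(u.segments) > 1:
        return [seg.atoms for seg in u.segments]
    if hasattr(u.atoms, "chainIDs"):
        cids = sorted(set(u.atoms.chainIDs))
        if len(cids) > 1:
            return [u.atoms[u.atoms.chainIDs == cid] for cid in cids]
    return [u.atoms]


def build_annotation(topology, role_config: Mapping | str | Path) -> ChannelAnnotation:
    """Map structural roles to atom indices per subunit.

    ``topology`` is a structure path or an MDAnalysis Universe.  The [sf]
    section either gives a sequence ``motif`` (searched per chain; each hit
    becomes one filter strand, so a two-pore dimer yields four strands from
    two chains) or explicit per-role selections.  Gate and species roles are
    plain selection strings.
    """
    mda = _import_mda()
    if isinstance(topology, (str, Path)):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(topology))
    else:
        u = topology
    cfg = _parse_role_config(role_config)
    sf_cfg = cfg.get("sf", {})
    motif = sf_cfg.get("motif", "TVGYG").upper()

    chains = [
        chain
        for chain in _chain_groups(u)
        if sum(r.resname.upper() in _AA3TO1 for r in chain.residues) >= len(motif)
    ]
    if not chains:
        raise AnnotationError("no protein chains found")
    strands = []  # list of residue-lists [T, V, G, Y, G]
    hits_per_chain = []
    for chain in chains:
        residues = chain.residues
        seq = "".join(_AA3TO1.get(r.resname.upper(), "X") for r in residues)
        starts = [i for i in range(len(seq) - len(motif) + 1) if seq[i : i + len(motif)] == motif]
        hits_per_chain.append(len(starts))
        if len(starts) == 0:
            raise AnnotationError(f"no {motif} motif found in chain of {len(residues)} residues")
        if len(starts) > 2:
            raise AnnotationError(f"ambiguous: {len(starts)} {motif} motifs in one chain")
        for s in starts:
            strands.append([residues[s + j] for j in range(len(motif))])
    if len(set(hits_per_chain)) != 1:
        raise AnnotationError(f"chains disagree on motif count: {hits_per_chain}")
    n_subunits = len(strands)
    if n_subunits not in (2, 4):
        raise AnnotationError(f"found {n_subunits} filter strands; expected 2 or 4")

    def atom_ix(residue, name: str) -> int:
        sel = residue.atoms[residue.atoms.names == name]
        if len(sel) != 1:
            raise AnnotationError(
                f"residue {residue.resname}{residue.resid}: expected one atom {name!r}, "
                f"found {len(sel)}"
            )
        return int(sel.ix[0])

    sf: dict[str, tuple[int, ...]] = {}
    role_atoms = {
        "T_OG1": (0, "OG1"), "T_O": (0, "O"), "V_O": (1, "O"), "G1_O": (2, "O"),
        "Y_O": (3, "O"), "G2_O": (4, "O"), "T_CA": (0, "CA"), "V_C": (1, "C"),
    }
    for role, (pos, name) in role_atoms.items():
        try:
            sf[role] = tuple(atom_ix(strand[pos], name) for strand in strands)
        except AnnotationError:
            if role in SF_ROLES:
                raise
            # extras (T_CA, V_C) are optional in minimal topologies
    # T59 CG: threonine side-chain methyl, if present
    try:
        sf["T59_CG"] = tuple(atom_ix(strand[0], "CG2") for strand in strands)
    except AnnotationError:
        pass

    gate: dict[str, tuple[int, ...]] = {}
    for role, selection in cfg.get("gate", {}).items():
        per_chain: list[int] = []
        for chain in chains:
            sel = chain.select_atoms(selection)
            per_chain.extend(int(i) for i in sel.ix)
        if per_chain:
            if len(per_chain) != n_subunits:
                raise AnnotationError(
                    f"gate role {role!r}: selected {len(per_chain)} atoms for "
                    f"{n_subunits} subunits"
                )
            gate[role] = tuple(per_chain)

    species = cfg.get("species", {})
    ion_sel = species.get("ion")
    wat_sel = species.get("water_oxygen")
    ions = u.select_atoms(ion_sel).ix if ion_sel else np.empty(0, dtype=int)
    waters = u.select_atoms(wat_sel).ix if wat_sel else np.empty(0, dtype=int)

    return ChannelAnnotation(
        n_subunits=n_subunits,
        sf=sf,
        gate=gate,
        ion_indices=np.asarray(ions, dtype=int),
        water_oxygen_indices=np.asarray(waters, dtype=int),
    )


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------


def write_tidy(records, path: str | Path, columns: Sequence[str] | None = None) -> Path:
    """Write records (list of mappings or a DataFrame) as a tidy CSV.

    One observation per row, long format.  Floats round-trip losslessly
    (full repr precision).  All records must share one schema; an empty
    record list with ``columns`` yields a header-only file.
    """
    path = Path(path)
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        records = list(records)
        if records:
            keys = list(records[0].keys())
            for r in records[1:]:
                if list(r.keys()) != keys:
                    raise SchemaError(
                        f"records disagree on schema: {keys} vs {list(r.keys())}"
                    )
            df = pd.DataFrame.from_records(records, columns=keys)
        else:
            df = pd.DataFrame(columns=list(columns) if columns else [])
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_tidy(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_ensemble(
    ensemble: TrajectoryEnsemble,
    topology: "TopologySpec",
    outdir: str | Path,
    structure_name: str = "structure.pdb",
) -> tuple[Path, list[Path]]:
    """Write a structure file plus one XTC per replica.

    ``topology`` supplies names/resnames/resids/chains (see
    :class:`TopologySpec`); coordinates are taken from the first frame of the
    first replica for the structure file.
    """
    mda = _import_mda()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    u = topology.to_universe()

    first = ensemble.replicas[0]
    u.atoms.positions = first.coords[0] / ANGSTROM_TO_NM
    u.dimensions = [*(first.box[0] / ANGSTROM_TO_NM * 10.0 * ANGSTROM_TO_NM), 90.0, 90.0, 90.0]
    structure = outdir / structure_name
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(structure))

    traj_paths = []
    for i, rep in enumerate(ensemble.replicas):
        traj = outdir / f"replica_{i:02d}.xtc"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with mda.Writer(str(traj), n_atoms=u.atoms.n_atoms) as w:
                for f in range(rep.n_frames):
                    u.atoms.positions = rep.coords[f] / ANGSTROM_TO_NM
                    u.dimensions = [*(rep.box[f] / ANGSTROM_TO_NM), 90.0, 90.0, 90.0]
                    u.trajectory.ts.time = rep.times[f] / PS_TO_NS
                    u.trajectory.ts.frame = f
                    w.write(u.atoms)
        traj_paths.append(traj)
    return structure, traj_paths


@dataclass
class TopologySpec:
    """Minimal atom-level topology used to round-trip synthetic systems."""

    names: list[str]
    resnames: list[str]
    resids: list[int]
    chains: list[str]

    def __post_init__(self) -> None:
        n = len(self.names)
        if not (len(self.resnames) == len(self.resids) == len(self.chains) == n):
            raise FormatError("topology arrays must have equal length")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def to_universe(self):
        mda = _import_mda()
        # Contiguous (chain, resid, resname) runs define residues.
        res_keys: list[tuple[str, int, str]] = []
        atom_resindex = []
        for name, rn, ri, ch in zip(self.names, self.resnames, self.resids, self.chains):
            key = (ch, ri, rn)
            if not res_keys or res_keys[-1] != key:
                res_keys.append(key)
            atom_resindex.append(len(res_keys) - 1)
        seg_keys: list[str] = []
        res_segindex = []
        for ch, _, _ in res_keys:
            if not seg_keys or seg_keys[-1] != ch:
                seg_keys.append(ch)
            res_segindex.append(len(seg_keys) - 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe.empty(
                n_atoms=self.n_atoms,
                n_residues=len(res_keys),
                n_segments=len(seg_keys),
                atom_resindex=np.asarray(atom_resindex),
                residue_segindex=np.asarray(res_segindex),
                trajectory=True,
            )
            u.add_TopologyAttr("names", self.names)
            u.add_TopologyAttr("resnames", [k[2] for k in res_keys])
            u.add_TopologyAttr("resids", [k[1] for k in res_keys])
            u.add_TopologyAttr("segids", seg_keys)
            u.add_TopologyAttr("chainIDs", [self.chains[i] for i in range(self.n_atoms)])
        return u
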