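"""File formats: DOS tables (TSV), conformations (XYZ), run configs (YAML).

All core outputs are plain text.  Energies are exact integers everywhere;
ln g is written with 15 significant digits; every output carries enough
header metadata to reconstruct the command that produced it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml

from .model import ChainConformation, ModelParams
from .moves import MoveSet
from .samc import DOSEstimate, SAMCSchedule

__all__ = [
    "DOSParseError",
    "XYZParseError",
    "RunConfig",
    "write_dos",
    "read_dos",
    "write_xyz",
    "read_xyz",
    "write_observables",
    "write_contact_matrix",
    "write_transitions",
]


class DOSParseError(ValueError):
    pass


class XYZParseError(ValueError):
    pass


def write_dos(path, dos: DOSEstimate) -> None:
    """TSV with '# key = value' header lines; columns energy, ln_g, visits."""
    path = Path(path)
    with path.open("w") as fh:
        for key, value in dos.metadata.items():
            fh.write(f"# {key} = {json.dumps(value)}\n")
        fh.write("# columns = energy\tln_g\tvisits\n")
        for e, lg, v in zip(dos.energies, dos.ln_g, dos.visits):
            fh.write(f"{int(e)}\t{lg:.15g}\t{int(v)}\n")


def read_dos(path) -> DOSEstimate:
    path = Path(path)
    metadata: dict = {}
    energies: list[int] = []
    ln_g: list[float] = []
    visits: list[int] = []
    warned_visits = False
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    key = key.strip()
                    if key == "columns":
                        continue
                    try:
                        metadata[key] = json.loads(value.strip())
                    except json.JSONDecodeError:
                        metadata[key] = value.strip()
                continue
            parts = line.split("\t")
            if len(parts) == 2:
                if not warned_visits:
                    warnings.warn(
                        f"{path}:{lineno}: no visits column; assuming visits=0",
                        stacklevel=2,
                    )
                    warned_visits = True
                parts = [*parts, "0"]
            if len(parts) != 3:
                raise DOSParseError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            try:
                e = int(parts[0])
                lg = float(parts[1])
                v = int(parts[2])
            except ValueError as exc:
                raise DOSParseError(f"{path}:{lineno}: {exc}") from exc
            if e in energies:
                raise DOSParseError(f"{path}:{lineno}: duplicate energy {e}")
            energies.append(e)
            ln_g.append(lg)
            visits.append(v)
    if not energies:
        raise DOSParseError(f"{path}: no data rows")
    order = np.argsort(energies)
    return DOSEstimate(
        np.array(energies)[order],
        np.array(ln_g)[order],
        np.array(visits)[order],
        metadata,
    )


def write_xyz(
    path,
    conf: ChainConformation,
    params: ModelParams | None = None,
    energy: int | None = None,
) -> None:
    """Standard XYZ: count line, metadata comment, one 'C x y z' per monomer."""
    path = Path(path)
    parts = []
    if params is not None:
        parts += [
            f"N={params.n_monomers}",
            f"L={params.bond_length:.17g}",
            f"lambda={params.well_width:.17g}",
        ]
    if energy is not None:
        parts.append(f"E={energy}")
    with path.open("w") as fh:
        fh.write(f"{conf.n_monomers}\n")
        fh.write(" ".join(parts) + "\n")
        for x, y, z in conf.coords:
            fh.write(f"C {x:.17g} {y:.17g} {z:.17g}\n")


def read_xyz(path) -> tuple[ChainConformation, dict]:
    """Returns the conformation plus any metadata parsed from the comment line."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise XYZParseError(f"{path}: empty file")
    try:
        count = int(lines[0].strip())
    except ValueError as exc:
        raise XYZParseError(f"{path}:1: first line must be the atom count") from exc
    if len(lines) < count + 2:
        raise XYZParseError(
            f"{path}: declared {count} atoms but file has {len(lines) - 2} coordinate lines"
        )
    meta: dict = {}
    for token in lines[1].split():
        if "=" in token:
            key, _, value = token.partition("=")
            try:
                meta[key] = int(value) if key in ("N", "E") else float(value)
            except ValueError:
                meta[key] = value
    coords = []
    for lineno, line in enumerate(lines[2 : 2 + count], start=3):
        parts = line.split()
        if len(parts) != 4:
            raise XYZParseError(f"{path}:{lineno}: expected 'El x y z'")
        coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
    if len(coords) != count:
        raise XYZParseError(f"{path}: atom-count mismatch")
    return ChainConformation(np.array(coords)), meta


def write_observables(path, obs, energies=None) -> None:
    """TSV of per-energy counts and mean R_g^2."""
    path = Path(path)
    if energies is None:
        energies = obs.energies
    with path.open("w") as fh:
        fh.write("# columns = energy\tcount\trg2_mean\n")
        for e in energies:
            c = obs.count(int(e))
            if c == 0:
                continue
            fh.write(f"{int(e)}\t{c}\t{obs.rg2_mean(int(e)):.15g}\n")


def write_contact_matrix(path, matrix: np.ndarray, header: str = "") -> None:
    """Dense contact (frequency) matrix as TSV."""
    path = Path(path)
    with path.open("w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for row in matrix:
            fh.write("\t".join(f"{x:.6g}" for x in row) + "\n")


def write_transitions(path, records) -> None:
    """Transition records as a small JSON document."""
    payload = []
    for r in records:
        payload.append(
            {
                "location": r.location,
                "variable": r.variable,
                "order": r.order,
                "diagnostics": r.diagnostics,
                "interval": list(r.interval) if r.interval else None,
            }
        )
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


@dataclass
class RunConfig:
    """Complete description of a simulation run; YAML round-trippable."""

    n_monomers: int = 20
    bond_length: float = 0.53
    well_width: float = 1.1
    n_steps: int = 10**6
    seed: int = 42
    gamma0: float = 1.0
    t0: int = 10**6
    grid_policy: str = "adaptive"
    observable_stride: int = 1
    collect_contacts: bool = True
    checkpoint_every: int | None = None
    pivot_weight: float = 1.0
    crankshaft_weight: float = 1.0
    end_weight: float = 1.0
    max_angle: float = float(np.pi)
    out_dos: str = "dos.tsv"
    out_observables: str | None = None

    def params(self) -> ModelParams:
        return ModelParams(self.n_monomers, self.bond_length, self.well_width)

    def schedule(self) -> SAMCSchedule:
        return SAMCSchedule(gamma0=self.gamma0, t0=self.t0)

    def move_set(self) -> MoveSet:
        return MoveSet(
            pivot_weight=self.pivot_weight,
            crankshaft_weight=self.crankshaft_weight,
            end_weight=self.end_weight,
            pivot_max_angle=self.max_angle,
            crankshaft_max_angle=self.max_angle,
            end_max_angle=self.max_angle,
        )

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        if isinstance(source, Path) or (
            isinstance(source, str) and "\n" not in source and Path(source).exists()
        ):
            data = yaml.safe_load(Path(source).read_text())
        else:
            data = yaml.safe_load(source)
        return cls(**data)
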