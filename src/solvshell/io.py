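"""Text-format I/O: extended XYZ, minimal PDB, labeling sidecars and curves.

Numeric output uses ``repr``-level precision so that written/reread pipelines
stay bit-stable for oracle comparisons.  The sidecar is a tab-separated table
mapping atom index (0-based, matching the XYZ body order) to site_class,
exchangeable flag, molecule id, residue and role; file output of PDB serials
is 1-based per convention.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .ensemble import Configuration, Ensemble, SimulationBox

__all__ = [
    "write_xyz", "read_xyz", "write_sidecar", "read_sidecar",
    "write_pdb", "write_curve", "read_curve", "write_matrix",
    "write_ensemble", "read_ensemble",
]


def write_xyz(config: Configuration, path) -> None:
    L = config.box.edge_lengths
    lines = [str(config.n_atoms),
             f'box="{L[0]!r} {L[1]!r} {L[2]!r}" periodic={config.box.periodic}']
    for el, p in zip(config.elements, config.positions):
        lines.append(f"{el} {float(p[0])!r} {float(p[1])!r} {float(p[2])!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz(path, sidecar=None) -> Configuration:
    lines = Path(path).read_text().splitlines()
    n = int(lines[0])
    comment = lines[1]
    box_part = comment.split('box="')[1].split('"')[0].split()
    periodic = "periodic=True" in comment
    box = SimulationBox(tuple(float(x) for x in box_part), periodic=periodic)
    elements, positions = [], []
    for line in lines[2:2 + n]:
        parts = line.split()
        elements.append(parts[0])
        positions.append([float(x) for x in parts[1:4]])
    positions = np.asarray(positions)
    if sidecar is not None:
        labels = read_sidecar(sidecar)
    else:
        labels = {
            "site_class": np.array(["Ow" if e == "O" else "Hw" for e in elements], dtype="U2"),
            "exchangeable": np.zeros(n, dtype=bool),
            "molecule_id": np.zeros(n, dtype=int),
            "residue": np.array(["water"] * n, dtype="U12"),
            "role": np.array([""] * n, dtype="U4"),
        }
    return Configuration(
        box=box, positions=positions,
        elements=np.array(elements, dtype="U2"),
        site_class=labels["site_class"], role=labels["role"],
        exchangeable=labels["exchangeable"],
        molecule_id=labels["molecule_id"], residue=labels["residue"])


def write_sidecar(config: Configuration, path) -> None:
    lines = ["# index\tsite_class\texchangeable\tmolecule_id\tresidue\trole"]
    for i in range(config.n_atoms):
        lines.append("\t".join([
            str(i), config.site_class[i], str(int(config.exchangeable[i])),
            str(int(config.molecule_id[i])), config.residue[i], config.role[i]]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_sidecar(path) -> dict:
    rows = [l.split("\t") for l in Path(path).read_text().splitlines()
            if l and not l.startswith("#")]
    rows.sort(key=lambda r: int(r[0]))
    return {
        "site_class": np.array([r[1] for r in rows], dtype="U2"),
        "exchangeable": np.array([bool(int(r[2])) for r in rows]),
        "molecule_id": np.array([int(r[3]) for r in rows], dtype=int),
        "residue": np.array([r[4] for r in rows], dtype="U12"),
        "role": np.array([r[5] if len(r) > 5 else "" for r in rows], dtype="U4"),
    }


def write_pdb(config: Configuration, path) -> None:
    """Minimal PDB: CRYST1 plus HETATM records with 1-based serials."""
    L = config.box.edge_lengths
    lines = [f"CRYST1{L[0]:9.3f}{L[1]:9.3f}{L[2]:9.3f}  90.00  90.00  90.00 P 1           1"]
    resname = {"water": "HOH", "reducing": "BGC", "non_reducing": "BGC"}
    for i in range(config.n_atoms):
        p = config.positions[i]
        name = (config.role[i] or config.elements[i])[:4]
        lines.append(
            f"HETATM{i + 1:5d} {name:<4s}{resname.get(config.residue[i], 'UNK'):>4s} A"
            f"{int(config.molecule_id[i]) % 10000 + 1:4d}    "
            f"{p[0]:8.3f}{p[1]:8.3f}{p[2]:8.3f}  1.00  0.00"
            f"          {config.elements[i]:>2s}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_curve(path, x, y, header: dict | None = None) -> None:
    """Two-column delimited text with '#' header lines naming the convention."""
    lines = [f"# {k}: {v}" for k, v in (header or {}).items()]
    lines += [f"{float(a)!r}\t{float(b)!r}" for a, b in zip(np.asarray(x), np.asarray(y))]
    Path(path).write_text("\n".join(lines) + "\n")


def read_curve(path):
    header, xs, ys = {}, [], []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            if ":" in line:
                k, v = line[1:].split(":", 1)
                header[k.strip()] = v.strip()
            continue
        if line.strip():
            a, b = line.split()
            xs.append(float(a))
            ys.append(float(b))
    return np.asarray(xs), np.asarray(ys), header


def write_matrix(path, m, header: dict | None = None) -> None:
    lines = [f"# {k}: {v}" for k, v in (header or {}).items()]
    for row in np.asarray(m):
        lines.append("\t".join(repr(float(v)) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def write_ensemble(ensemble: Ensemble, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_sidecar(ensemble.configurations[0], directory / "labels.tsv")
    for i, cfg in enumerate(ensemble.configurations):
        write_xyz(cfg, directory / f"config_{i:05d}.xyz")


def read_ensemble(directory) -> Ensemble:
    directory = Path(directory)
    sidecar = directory / "labels.tsv"
    paths = sorted(directory.glob("config_*.xyz"))
    if not paths:
        raise FileNotFoundError(f"no config_*.xyz files under {directory}")
    return Ensemble([read_xyz(p, sidecar) for p in paths])
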