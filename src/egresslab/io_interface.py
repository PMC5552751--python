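"""File formats and run configuration.

Canonical trajectory format is multi-frame XYZ (element column derived
from atom roles); PDB files are read-only sources of C-alpha coordinates
for external structures.  Bias and CV records use PLUMED-flavoured
plain-text tables: COLVAR (time, s, sigma, z[, bias]) and HILLS (time,
center, width, height), tab-separated with one '#'-prefixed header line.
Run configurations are JSON with strictly validated keys.

Conventions: coordinates in A; frames numbered from 1 in reports; atom
indices in configs are 0-based.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path as FsPath

import numpy as np

from .exceptions import ConfigurationError, ParseError
from .toysim import Conformation

__all__ = [
    "read_xyz",
    "write_xyz",
    "read_pdb_calpha",
    "write_colvar",
    "read_colvar",
    "write_hills",
    "read_hills",
    "load_config",
]

_ROLE_ELEMENT = {"ligand": "C", "protein": "N", "anchor": "Fe"}


def _elements_for(system) -> list:
    return [_ROLE_ELEMENT[a.role] for a in system.atoms]


def write_xyz(confs, path, system=None, elements=None) -> None:
    """Write conformations as multi-frame XYZ (6 decimal places).

    The element column comes from ``elements``, from the system's atom
    roles, or defaults to 'X'.
    """
    confs = list(confs)
    with open(path, "w") as fh:
        for conf in confs:
            coords = np.atleast_2d(np.asarray(conf.coordinates, float))
            if coords.shape[1] != 3:
                raise ConfigurationError("XYZ output needs (n,3) coordinates")
            if elements is not None:
                els = elements
            elif system is not None:
                els = _elements_for(system)
            else:
                els = ["X"] * coords.shape[0]
            fh.write(f"{coords.shape[0]}\n")
            label = conf.label.replace("\n", " ")
            fh.write(f"t= {conf.time:.6f} {label}\n")
            for el, row in zip(els, coords):
                fh.write(f"{el} {row[0]:.6f} {row[1]:.6f} {row[2]:.6f}\n")


def read_xyz(path) -> list:
    """Read a multi-frame XYZ file into Conformations.

    Empty files give an empty list with a warning; a malformed header or a
    count/body mismatch raises :class:`ParseError` naming the line."""
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not any(l.strip() for l in lines):
        warnings.warn(f"{path}: empty XYZ file", RuntimeWarning, stacklevel=2)
        return frames
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ParseError(f"{path}: line {i + 1}: expected atom count, got "
                             f"{lines[i]!r} (frame {len(frames) + 1})")
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        body = lines[i + 2:i + 2 + n]
        if len(body) < n:
            raise ParseError(f"{path}: frame {len(frames) + 1} declares {n} atoms "
                             f"but only {len(body)} rows follow (line {i + 1})")
        coords = np.empty((n, 3))
        for j, row in enumerate(body):
            parts = row.split()
            if len(parts) < 4:
                raise ParseError(f"{path}: line {i + 3 + j}: malformed atom row "
                                 f"in frame {len(frames) + 1}")
            coords[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
        t = 0.0
        label = comment.strip()
        toks = comment.split()
        if len(toks) >= 2 and toks[0] == "t=":
            try:
                t = float(toks[1])
                label = " ".join(toks[2:])
            except ValueError:
                pass
        frames.append(Conformation(coords, time=t, label=label))
        i += 2 + n
    return frames


def read_pdb_calpha(path, include_hetatm: bool = False):
    """Extract C-alpha coordinates from a PDB file, in file order.

    altLoc duplicates keep the first occurrence; HETATM records are ignored
    unless requested.  Returns (Conformation, residue_labels)."""
    import biotite.structure.io.pdb as pdb

    arr = pdb.PDBFile.read(str(path)).get_structure(model=1, altloc="first")
    if not include_hetatm:
        arr = arr[~arr.hetero]
    ca = arr[arr.atom_name == "CA"]
    if ca.array_length() == 0:
        raise ParseError(f"{path}: no C-alpha atoms found")
    labels = [f"{ch}:{res}{num}" for ch, res, num in
              zip(ca.chain_id, ca.res_name, ca.res_id)]
    return Conformation(np.asarray(ca.coord, float)), labels


def write_colvar(rows, path, has_bias: bool = False) -> None:
    """COLVAR-style table.  Columns: time[ps] s sigma z[A^2] (bias[kcal/mol])."""
    cols = ["time[ps]", "s", "sigma", "z[A^2]"] + (["bias[kcal/mol]"] if has_bias else [])
    with open(path, "w") as fh:
        fh.write("# " + "\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(f"{v:.9g}" for v in row) + "\n")


def read_colvar(path) -> np.ndarray:
    data = np.loadtxt(path, comments="#", ndmin=2)
    return data


def write_hills(kernels, path) -> None:
    """HILLS-style table.  Columns: time[ps] center width height[kcal/mol]."""
    with open(path, "w") as fh:
        fh.write("# time[ps]\tcenter\twidth\theight[kcal/mol]\n")
        for k in kernels:
            fh.write(f"{k.deposit_time:.9g}\t{k.center:.12g}\t"
                     f"{k.width:.12g}\t{k.height:.12g}\n")


def read_hills(path):
    """Read a HILLS file back into GaussianKernel objects."""
    from .wt_metad import GaussianKernel

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # header-only files
        data = np.loadtxt(path, comments="#", ndmin=2)
    if data.size == 0:
        return []
    return [GaussianKernel(c, w, h, t) for t, c, w, h in data]


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_SCHEMA = {
    "system": {"kind", "n_cage", "cage_radius", "n_tunnels", "seed",
               "tunnel_half_angle_deg", "barrier", "spacing", "xyz_file"},
    "dynamics": {"temperature", "friction", "dt", "steps", "seed"},
    "pathsearch": {"gaussian_width", "include_gamma", "candidate_count",
                   "sphere_radius", "local_refine_steps", "seed",
                   "segment_steps", "bias_force_magnitude",
                   "termination_distance", "max_nodes"},
    "metad": {"initial_height", "deposit_interval", "delta_t", "z_limit",
              "z_kappa", "grid_min", "grid_max", "n_grid", "adaptive_window",
              "width_floor", "steps", "seed"},
    "cluster": {"eps", "min_pts", "subset"},
}

_RANGES = {
    ("dynamics", "temperature"): (1.0, 1e4),
    ("dynamics", "dt"): (1e-5, 0.1),
    ("metad", "delta_t"): (1.0, 1e6),
}


def load_config(path) -> dict:
    """Load and validate a JSON run configuration.

    Unknown blocks or keys are rejected; a handful of physical parameters
    are range-checked.  Missing blocks are filled with empty dicts.
    """
    p = FsPath(path)
    if not p.exists():
        raise ConfigurationError(f"config file not found: {path}")
    try:
        cfg = json.loads(p.read_text())
    except json.JSONDecodeError as exc:
        raise ConfigurationError(f"{path}: invalid JSON ({exc})") from exc
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"{path}: top level must be an object")
    for block, content in cfg.items():
        if block not in _SCHEMA:
            raise ConfigurationError(f"{path}: unknown config block {block!r}")
        if not isinstance(content, dict):
            raise ConfigurationError(f"{path}: block {block!r} must be an object")
        unknown = set(content) - _SCHEMA[block]
        if unknown:
            raise ConfigurationError(
                f"{path}: unknown keys in {block!r}: {sorted(unknown)}")
        for key, val in content.items():
            rng = _RANGES.get((block, key))
            if rng and not (rng[0] <= float(val) <= rng[1]):
                raise ConfigurationError(
                    f"{path}: {block}.{key} = {val} outside [{rng[0]}, {rng[1]}]")
    for block in _SCHEMA:
        cfg.setdefault(block, {})
    return cfg
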