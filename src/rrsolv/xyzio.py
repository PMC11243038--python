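"""File formats: multi-frame XYZ for solvated spheres, JSON for chromophores.

The XYZ dialect is standard (atom-count line, comment line, ``label x y z``
records) with the comment line carrying frame metadata as ``key=value``
pairs: ``frame=<i> radius=<Å> nsolute=<n> time=<t> exclusion=<Å>``.  Solute
atoms come first (their labels are the template site labels), followed by
waters as consecutive O, H, H triples.  Point charges are not representable
in XYZ; pass a :class:`~rrsolv.synthetic.SoluteTemplate` to
:func:`read_frames` to restore them.

Chromophore models are serialized as a schema-versioned JSON document.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np

from .synthetic import (ChromophoreModel, ExcitedState, SolvatedFrame,
                        SoluteTemplate)

logger = logging.getLogger(__name__)

CHROMOPHORE_SCHEMA = "rrsolv-chromophore-1"


class FormatError(ValueError):
    """Malformed frame file; the message carries the offending line number."""


def write_frames(frames: Sequence[SolvatedFrame], path: str | Path) -> None:
    """Write frames as multi-frame XYZ (coordinates to 1e-10 Å)."""
    path = Path(path)
    with path.open("w") as fh:
        for fr in frames:
            n = len(fr.solute.labels) + 3 * fr.n_waters
            fh.write(f"{n}\n")
            fh.write(f"frame={fr.frame_index} radius={fr.radius:.6f} "
                     f"nsolute={len(fr.solute.labels)} time={fr.time:.6f} "
                     f"exclusion={fr.exclusion:.6f}\n")
            for lbl, xyz in zip(fr.solute.labels, fr.solute.coords):
                fh.write(f"{lbl} {xyz[0]:.10f} {xyz[1]:.10f} {xyz[2]:.10f}\n")
            for w in fr.waters:
                for lbl, xyz in zip(("O", "H", "H"), w):
                    fh.write(f"{lbl} {xyz[0]:.10f} {xyz[1]:.10f} {xyz[2]:.10f}\n")


def read_frames(path: str | Path,
                solute: SoluteTemplate | None = None) -> list[SolvatedFrame]:
    """Read a multi-frame XYZ file written by :func:`write_frames`.

    When ``solute`` is given, its labels must match the file's solute block
    and its charges/acceptors are attached to the returned frames; otherwise
    a chargeless template with no acceptor sites is reconstructed from the
    file.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    frames: list[SolvatedFrame] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            logger.info("%s: blank line at %d skipped", path.name, i + 1)
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError:
            raise FormatError(f"{path.name}:{i + 1}: malformed atom count "
                              f"{lines[i].strip()!r}") from None
        if i + 1 >= len(lines):
            raise FormatError(f"{path.name}:{i + 2}: missing comment line")
        meta = _parse_comment(lines[i + 1], path.name, i + 2)
        nsolute = int(meta.get("nsolute", 0))
        if (natoms - nsolute) % 3 != 0:
            raise FormatError(f"{path.name}:{i + 1}: atom count {natoms} minus "
                              f"nsolute {nsolute} is not a whole number of waters")
        block = lines[i + 2: i + 2 + natoms]
        if len(block) < natoms:
            raise FormatError(f"{path.name}:{i + 2 + len(block)}: frame truncated "
                              f"(expected {natoms} atom records)")
        labels, coords = [], []
        for k, ln in enumerate(block):
            parts = ln.split()
            if len(parts) != 4:
                raise FormatError(f"{path.name}:{i + 3 + k}: expected "
                                  f"'label x y z', got {ln!r}")
            try:
                coords.append([float(p) for p in parts[1:]])
            except ValueError:
                raise FormatError(f"{path.name}:{i + 3 + k}: non-numeric "
                                  f"coordinate in {ln!r}") from None
            labels.append(parts[0])
        coords = np.asarray(coords)
        sol_labels = tuple(labels[:nsolute])
        if solute is not None:
            if tuple(solute.labels) != sol_labels:
                raise FormatError(f"{path.name}: solute labels in file do not "
                                  f"match the supplied template")
            template = SoluteTemplate(
                labels=solute.labels, coords=coords[:nsolute],
                charges=solute.charges, acceptors=solute.acceptors,
                total_charge=solute.total_charge,
                excited_charges=solute.excited_charges)
        else:
            template = SoluteTemplate(
                labels=sol_labels, coords=coords[:nsolute],
                charges=np.zeros(nsolute), acceptors=(), total_charge=0.0)
        waters = coords[nsolute:].reshape(-1, 3, 3)
        frames.append(SolvatedFrame(
            solute=template, waters=waters,
            radius=float(meta.get("radius", 0.0)),
            frame_index=int(meta.get("frame", len(frames))),
            time=float(meta.get("time", 0.0)),
            exclusion=float(meta.get("exclusion", 0.0)),
        ))
        i += 2 + natoms
    return frames


def _parse_comment(line: str, name: str, lineno: int) -> dict:
    meta = {}
    for tok in line.split():
        if "=" in tok:
            k, v = tok.split("=", 1)
            meta[k] = v
    if "radius" not in meta:
        raise FormatError(f"{name}:{lineno}: comment line must carry "
                          f"frame=<i> radius=<Å> metadata, got {line!r}")
    return meta


# --------------------------------------------------------------------------
# chromophore JSON
# --------------------------------------------------------------------------

def model_to_dict(model: ChromophoreModel) -> dict:
    return {
        "masses_amu": model.masses_amu.tolist(),
        "modes": model.modes.tolist(),
        "freqs_cm": model.freqs_cm.tolist(),
        "alpha_deriv": model.alpha_deriv.tolist(),
        "gamma_deriv": model.gamma_deriv.tolist(),
        "mode_labels": list(model.mode_labels),
        "snapshot_index": model.snapshot_index,
        "states": [
            {
                "energy_cm": s.energy_cm,
                "osc_strength": s.osc_strength,
                "trans_dipole_au": s.trans_dipole_au,
                "gradient_au": s.gradient_au.tolist(),
                "index": s.index,
            }
            for s in model.states
        ],
    }


def model_from_dict(d: dict) -> ChromophoreModel:
    states = tuple(
        ExcitedState(energy_cm=s["energy_cm"], osc_strength=s["osc_strength"],
                     trans_dipole_au=s["trans_dipole_au"],
                     gradient_au=np.asarray(s["gradient_au"]),
                     index=s["index"])
        for s in d["states"])
    return ChromophoreModel(
        masses_amu=np.asarray(d["masses_amu"]),
        modes=np.asarray(d["modes"]),
        freqs_cm=np.asarray(d["freqs_cm"]),
        alpha_deriv=np.asarray(d["alpha_deriv"]),
        gamma_deriv=np.asarray(d["gamma_deriv"]),
        states=states, snapshot_index=d.get("snapshot_index", 0),
        mode_labels=tuple(d.get("mode_labels", ())))


def save_models(models: Sequence[ChromophoreModel], path: str | Path) -> None:
    doc = {"schema": CHROMOPHORE_SCHEMA,
           "models": [model_to_dict(m) for m in models]}
    Path(path).write_text(json.dumps(doc))


def load_models(path: str | Path) -> list[ChromophoreModel]:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema") != CHROMOPHORE_SCHEMA:
        raise FormatError(f"unsupported chromophore schema {doc.get('schema')!r}")
    return [model_from_dict(d) for d in doc["models"]]
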