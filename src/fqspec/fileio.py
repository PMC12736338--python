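"""Reading and writing the pipeline's on-disk formats.

Coordinates go through MDAnalysis (multi-frame XYZ, per-snapshot PDB);
tabular data (stick spectra, curves, embedding solutions) through pandas
CSV; small metadata through JSON.  Every writer here has a matching
reader, and the round trip is exercised in the test-suite.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import EmbeddingSolution, MMTopology
from .spectra import SpectrumCurve, StickSpectrum
from .trajectory import RCNCurve, RDFCurve, Snapshot

__all__ = [
    "write_snapshots_xyz",
    "read_snapshots_xyz",
    "write_snapshot_pdb",
    "read_snapshot_pdb",
    "write_sticks_csv",
    "read_sticks_csv",
    "write_curve_csv",
    "read_curve_csv",
    "write_rdf_csv",
    "write_rcn_csv",
    "write_solution_csv",
    "write_json",
    "read_json",
    "plot_curve",
    "plot_rdf",
    "read_solute_xyzq",
]


def _mda():
    import MDAnalysis as mda

    return mda


# ---------------------------------------------------------------------------
# Coordinates
# ---------------------------------------------------------------------------


def _snapshot_universe(snapshot: Snapshot):
    """Build an MDAnalysis Universe for one snapshot (solute + waters)."""
    mda = _mda()
    n_solute = len(snapshot.solute_labels)
    n_atoms = n_solute + 3 * snapshot.n_waters
    n_res = 1 + snapshot.n_waters
    resindex = np.concatenate(
        [np.zeros(n_solute, dtype=int),
         np.repeat(np.arange(1, n_res), 3)]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n_atoms, n_residues=n_res, atom_resindex=resindex, trajectory=True
        )
        u.add_TopologyAttr("names", snapshot.all_labels())
        u.add_TopologyAttr(
            "elements",
            [lab[0].upper() for lab in snapshot.all_labels()],
        )
        u.add_TopologyAttr("resnames", ["LIG"] + ["SOL"] * snapshot.n_waters)
        u.add_TopologyAttr("resids", list(range(1, n_res + 1)))
        u.atoms.positions = snapshot.all_coords()
    return u


def write_snapshots_xyz(snapshots: list[Snapshot], path: str | Path) -> None:
    """Write an ensemble as multi-frame XYZ plus a JSON sidecar map.

    All snapshots must share the same site count (true for a fixed
    generator config).  The sidecar ``<path>.map.json`` records the
    solute labels and water count needed to regroup sites on read.
    """
    path = Path(path)
    counts = {len(s.solute_labels) + 3 * s.n_waters for s in snapshots}
    if len(counts) != 1:
        raise ValueError("multi-frame XYZ requires a uniform site count")
    mda = _mda()
    u = _snapshot_universe(snapshots[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), u.atoms.n_atoms) as w:
            for snap in snapshots:
                u.atoms.positions = snap.all_coords()
                w.write(u.atoms)
    sidecar = {
        "solute_labels": list(snapshots[0].solute_labels),
        "solvent_labels": list(snapshots[0].solvent_labels),
        "n_waters": snapshots[0].n_waters,
        "snapshot_ids": [s.snapshot_id for s in snapshots],
    }
    write_json(sidecar, path.with_suffix(path.suffix + ".map.json"))


def read_snapshots_xyz(path: str | Path, sidecar: str | Path | None = None
                       ) -> list[Snapshot]:
    """Read a multi-frame XYZ ensemble written by :func:`write_snapshots_xyz`."""
    path = Path(path)
    if sidecar is None:
        sidecar = path.with_suffix(path.suffix + ".map.json")
    meta = read_json(sidecar)
    n_solute = len(meta["solute_labels"])
    mda = _mda()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        snapshots = []
        ids = meta.get("snapshot_ids") or list(range(len(u.trajectory)))
        for k, _ in enumerate(u.trajectory):
            coords = u.atoms.positions.astype(float)
            snapshots.append(
                Snapshot(
                    solute_labels=list(meta["solute_labels"]),
                    solute_coords=coords[:n_solute],
                    solvent_coords=coords[n_solute:].reshape(-1, 3, 3),
                    solvent_labels=tuple(meta["solvent_labels"]),
                    snapshot_id=int(ids[k]),
                )
            )
    return snapshots


def write_snapshot_pdb(snapshot: Snapshot, path: str | Path) -> None:
    """Write one snapshot as PDB; waters are SOL residues, solute is LIG."""
    u = _snapshot_universe(snapshot)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def read_snapshot_pdb(path: str | Path) -> Snapshot:
    """Read a snapshot from PDB; molecule grouping from residue numbering."""
    mda = _mda()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    sol = u.select_atoms("resname SOL")
    lig = u.select_atoms("not resname SOL")
    waters = []
    labels = ("OW", "HW1", "HW2")
    for res in sol.residues:
        if len(res.atoms) != 3:
            raise ValueError(f"water residue {res.resid} has {len(res.atoms)} sites")
        waters.append(res.atoms.positions.astype(float))
    return Snapshot(
        solute_labels=[a.name for a in lig.atoms],
        solute_coords=lig.positions.astype(float),
        solvent_coords=np.array(waters) if waters else np.zeros((0, 3, 3)),
        solvent_labels=labels,
    )


def read_solute_xyzq(path: str | Path) -> list[tuple[np.ndarray, float, str]]:
    """Read an XYZ-like solute file whose 4th column is the point charge.

    Format per line: ``label x y z charge`` (Angstrom, a.u.); blank lines
    and ``#`` comments ignored.  Returns (position, charge, label) rows.
    """
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#")[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(f"expected 'label x y z q', got {line!r}")
        lab, x, y, z, q = parts
        rows.append((np.array([float(x), float(y), float(z)]), float(q), lab))
    return rows


# ---------------------------------------------------------------------------
# Tabular data
# ---------------------------------------------------------------------------


def write_sticks_csv(sticks: list[StickSpectrum], path: str | Path) -> None:
    rows = [
        {"snapshot_id": s.snapshot_id, "energy_eV": e, "strength": f}
        for s in sticks
        for e, f in s.transitions
    ]
    pd.DataFrame(rows, columns=["snapshot_id", "energy_eV", "strength"]).to_csv(
        path, index=False
    )


def read_sticks_csv(path: str | Path) -> list[StickSpectrum]:
    df = pd.read_csv(path)
    out = []
    for sid, grp in df.groupby("snapshot_id", sort=True):
        out.append(
            StickSpectrum(
                transitions=list(zip(grp["energy_eV"], grp["strength"])),
                snapshot_id=int(sid),
            )
        )
    return out


def write_curve_csv(curve: SpectrumCurve, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# fwhm_eV={curve.fwhm}\n# n_snapshots={curve.n_snapshots}\n")
        pd.DataFrame(
            {"energy_eV": curve.energies, "intensity": curve.intensity}
        ).to_csv(fh, index=False)


def read_curve_csv(path: str | Path) -> SpectrumCurve:
    import io

    meta = {}
    lines = Path(path).read_text().splitlines(keepends=True)
    body_start = 0
    for line in lines:
        if not line.startswith("#"):
            break
        key, _, val = line[1:].strip().partition("=")
        meta[key.strip()] = val.strip()
        body_start += 1
    df = pd.read_csv(io.StringIO("".join(lines[body_start:])))
    return SpectrumCurve(
        energies=df["energy_eV"].to_numpy(),
        intensity=df["intensity"].to_numpy(),
        fwhm=float(meta.get("fwhm_eV", "nan")),
        n_snapshots=int(meta.get("n_snapshots", "1")),
    )


def write_rdf_csv(rdf: RDFCurve, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# pair={rdf.pair_label[0]}-{rdf.pair_label[1]}"
            f" bulk_density_A3={rdf.bulk_density}\n"
        )
        pd.DataFrame({"r_A": rdf.r_centers, "g": rdf.g}).to_csv(fh, index=False)


def write_rcn_csv(rcn: RCNCurve, path: str | Path) -> None:
    pd.DataFrame({"r_A": rcn.r_centers, "n": rcn.n}).to_csv(path, index=False)


def write_solution_csv(
    solution: EmbeddingSolution, topology: MMTopology, path: str | Path
) -> None:
    """Per-site charges and dipoles: index, q, mux, muy, muz, molecule id."""
    n = topology.n_sites
    mu = solution.dipoles if solution.dipoles is not None else np.zeros((n, 3))
    pd.DataFrame(
        {
            "site": np.arange(n),
            "q": solution.charges,
            "mux": mu[:, 0],
            "muy": mu[:, 1],
            "muz": mu[:, 2],
            "molecule_id": [s.molecule_id for s in topology.sites],
        }
    ).to_csv(path, index=False)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def plot_curve(curve: SpectrumCurve, path: str | Path, title: str = "") -> None:
    """Save a broadened-spectrum plot (PNG/PDF by extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(curve.energies, curve.intensity, lw=1.2)
    ax.set_xlabel("energy (eV)")
    ax.set_ylabel("intensity (arb. u.)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_rdf(rdf: RDFCurve, rcn: RCNCurve | None, path: str | Path) -> None:
    """Save a g(r) plot, optionally with the running coordination inset."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(rdf.r_centers, rdf.g, lw=1.2)
    ax.set_xlabel("r (Å)")
    ax.set_ylabel(f"g(r) {rdf.pair_label[0]}–{rdf.pair_label[1]}")
    if rcn is not None:
        ins = ax.inset_axes([0.55, 0.5, 0.42, 0.45])
        ins.plot(rcn.r_centers, rcn.n, lw=1.0)
        ins.set_ylabel("n(r)", fontsize=8)
        ins.tick_params(labelsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer, np.floating)):
        return o.item()
    raise TypeError(f"not JSON-serialisable: {type(o)}")
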