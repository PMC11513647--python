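"""Reading and writing matrix bundles, trees and trait tables.

A matrix bundle is one directory per dataset:

* ``index.csv`` with columns ``species_id, matrix_file, P, sociality,
  body_mass_g, wild, unmanipulated, extant`` (one row per matrix; several
  rows may share a species, in which case the pipeline takes their grand
  mean);
* per matrix a CSV triplet ``<id>.A.csv``, ``<id>.U.csv``, ``<id>.F.csv``
  with the stage labels as header row (``matrix_file`` names the ``<id>``
  prefix);
* optionally ``tree.nwk``, a Newick phylogeny whose tip labels match
  ``species_id``.

:func:`write_bundle` and :func:`read_bundle` round-trip
:class:`~phylodem.synthetic.SpeciesRecord` lists through this layout.
"""

from __future__ import annotations

from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .mpm import MatrixPopulationModel
from .synthetic import SpeciesRecord

INDEX_COLUMNS = [
    "species_id",
    "matrix_file",
    "P",
    "sociality",
    "body_mass_g",
    "wild",
    "unmanipulated",
    "extant",
]


def _write_matrix(path: Path, M: np.ndarray, labels) -> None:
    pd.DataFrame(M, columns=list(labels)).to_csv(path, index=False)


def _read_matrix(path: Path) -> tuple[np.ndarray, tuple[str, ...]]:
    df = pd.read_csv(path)
    return df.to_numpy(dtype=float), tuple(df.columns)


def write_bundle(
    records: list[SpeciesRecord],
    path: str | Path,
    tree: dendropy.Tree | None = None,
) -> Path:
    """Write species records (and optionally a tree) as a matrix bundle."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        m = rec.mpm
        stem = rec.species_id
        for part, M in (("A", m.A), ("U", m.U), ("F", m.F)):
            _write_matrix(path / f"{stem}.{part}.csv", M, m.stage_labels)
        rows.append(
            {
                "species_id": rec.species_id,
                "matrix_file": stem,
                "P": m.interval,
                "sociality": rec.sociality,
                "body_mass_g": rec.adult_body_mass,
                "wild": m.wild,
                "unmanipulated": m.unmanipulated,
                "extant": m.extant,
            }
        )
    pd.DataFrame(rows, columns=INDEX_COLUMNS).to_csv(
        path / "index.csv", index=False
    )
    if tree is not None:
        tree.write(path=str(path / "tree.nwk"), schema="newick")
    return path


def read_bundle(
    path: str | Path,
) -> tuple[list[SpeciesRecord], dendropy.Tree | None]:
    """Read a matrix bundle back into species records (and its tree)."""
    path = Path(path)
    index = pd.read_csv(path / "index.csv")
    records: list[SpeciesRecord] = []
    for _, row in index.iterrows():
        stem = str(row["matrix_file"])
        A, labels = _read_matrix(path / f"{stem}.A.csv")
        U, _ = _read_matrix(path / f"{stem}.U.csv")
        F, _ = _read_matrix(path / f"{stem}.F.csv")
        mpm = MatrixPopulationModel(
            A=A,
            U=U,
            F=F,
            stage_labels=labels,
            interval=float(row["P"]),
            species_id=str(row["species_id"]),
            wild=bool(row["wild"]),
            unmanipulated=bool(row["unmanipulated"]),
            extant=bool(row["extant"]),
        )
        records.append(
            SpeciesRecord(
                species_id=str(row["species_id"]),
                mpm=mpm,
                sociality=int(row["sociality"]),
                adult_body_mass=float(row["body_mass_g"]),
            )
        )
    tree = None
    tree_path = path / "tree.nwk"
    if tree_path.exists():
        tree = dendropy.Tree.get(
            path=str(tree_path), schema="newick", preserve_underscores=True
        )
    return records, tree


def write_trait_table(table: pd.DataFrame, path: str | Path) -> None:
    """Trait table CSV: one row per species, missing values as empty cells."""
    table.to_csv(path, index=True, index_label="species_id", na_rep="")


def read_trait_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="species_id")
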