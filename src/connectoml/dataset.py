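"""The ``ConnectomeDataset`` container and its on-disk formats.

A dataset is a subjects × edges matrix of wPLI values for one frequency band,
together with binary group labels (case vs control), an :class:`~connectoml.edges.EdgeIndex`
carrying the region names, and the global edge ids of its columns (so that a
filtered dataset remembers which atlas edges it kept).

Two interchangeable text formats are supported:

``square_csv``
    A directory with one ``<subject>.csv`` per subject — the full symmetric
    matrix with region names as header — plus a ``labels.json`` sidecar
    mapping subject id to group name.
``edge_table_csv``
    A single long-format CSV with columns
    ``subject_id, group, band, region_a, region_b, wpli``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .edges import EdgeIndex, devectorize, vectorize_matrix

__all__ = ["ConnectomeDataset", "read_dataset", "write_dataset"]

CONTROL, CASE = 0, 1
_VALUE_TOL = 1e-9


@dataclass
class ConnectomeDataset:
    """Subjects × edges matrix for one band, with labels and edge identities.

    ``labels`` is an int array with 0 = control, 1 = case; ``group_names``
    maps those codes to the names used on disk. ``edge_ids`` are the columns'
    global edge ids under ``edge_index`` (``arange(E)`` for an unfiltered
    dataset).
    """

    subject_ids: list[str]
    labels: np.ndarray
    band: str
    X: np.ndarray
    edge_index: EdgeIndex
    edge_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    group_names: tuple[str, str] = ("control", "PTSD")

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.edge_ids is None:
            self.edge_ids = np.arange(self.edge_index.n_edges)
        self.edge_ids = np.asarray(self.edge_ids, dtype=int)
        self.validate()

    def validate(self) -> None:
        n, e = self.X.shape
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length does not match X rows")
        if len(set(self.subject_ids)) != n:
            raise ValueError("subject ids must be unique")
        if self.labels.shape != (n,):
            raise ValueError("labels length does not match X rows")
        if not set(np.unique(self.labels)) <= {CONTROL, CASE}:
            raise ValueError("labels must be 0 (control) or 1 (case)")
        if len(self.edge_ids) != e:
            raise ValueError("edge_ids length does not match X columns")
        if e and (self.edge_ids.min() < 0 or self.edge_ids.max() >= self.edge_index.n_edges):
            raise ValueError("edge_ids out of range for edge_index")
        if np.isnan(self.X).any():
            raise ValueError("X contains missing values")
        if e and (self.X.min() < -_VALUE_TOL or self.X.max() > 1 + _VALUE_TOL):
            raise ValueError(
                f"wPLI values must lie in [0, 1]; found range "
                f"[{self.X.min():.6g}, {self.X.max():.6g}]"
            )

    # -- basic views ---------------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_edges(self) -> int:
        return self.X.shape[1]

    @property
    def is_empty_selection(self) -> bool:
        """True when every edge column has been filtered away (no-signal)."""
        return self.n_edges == 0

    def class_counts(self) -> tuple[int, int]:
        """(n_control, n_case)."""
        return int((self.labels == CONTROL).sum()), int((self.labels == CASE).sum())

    def edge_labels(self) -> list[str]:
        return [self.edge_index.edge_label(int(e)) for e in self.edge_ids]

    def select_edges(self, edge_ids) -> "ConnectomeDataset":
        """Restrict to the given *global* edge ids (kept in index order)."""
        wanted = np.asarray(sorted(set(int(e) for e in edge_ids)), dtype=int)
        pos = {int(e): c for c, e in enumerate(self.edge_ids)}
        missing = [int(e) for e in wanted if int(e) not in pos]
        if missing:
            raise KeyError(f"edges not present in dataset: {missing[:5]}")
        cols = np.array([pos[int(e)] for e in wanted], dtype=int)
        return ConnectomeDataset(
            subject_ids=list(self.subject_ids),
            labels=self.labels.copy(),
            band=self.band,
            X=self.X[:, cols] if len(cols) else np.empty((self.n_subjects, 0)),
            edge_index=self.edge_index,
            edge_ids=wanted,
            group_names=self.group_names,
        )

    def select_subjects(self, subject_ids) -> "ConnectomeDataset":
        order = {s: r for r, s in enumerate(self.subject_ids)}
        missing = [s for s in subject_ids if s not in order]
        if missing:
            raise KeyError(f"unknown subjects: {missing[:5]}")
        rows = np.array([order[s] for s in subject_ids], dtype=int)
        return ConnectomeDataset(
            subject_ids=list(subject_ids),
            labels=self.labels[rows],
            band=self.band,
            X=self.X[rows],
            edge_index=self.edge_index,
            edge_ids=self.edge_ids.copy(),
            group_names=self.group_names,
        )

    # -- long-format helper --------------------------------------------------

    def to_edge_table(self) -> pd.DataFrame:
        names = self.edge_index.region_names
        pairs = self.edge_index.pairs[self.edge_ids]
        frames = []
        for row, sid in enumerate(self.subject_ids):
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": sid,
                        "group": self.group_names[self.labels[row]],
                        "band": self.band,
                        "region_a": [names[i] for i, _ in pairs],
                        "region_b": [names[j] for _, j in pairs],
                        "wpli": self.X[row],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


# -- IO ----------------------------------------------------------------------


def _labels_from_mapping(subject_ids, mapping, case_label: str) -> tuple[np.ndarray, tuple[str, str]]:
    groups = {str(g) for g in mapping.values()}
    if len(groups) != 2:
        raise ValueError(f"expected exactly two groups, found {sorted(groups)}")
    if case_label not in groups:
        raise ValueError(f"case label {case_label!r} not among groups {sorted(groups)}")
    control_label = next(g for g in sorted(groups) if g != case_label)
    missing = [s for s in subject_ids if s not in mapping]
    if missing:
        raise ValueError(f"subjects without a label: {missing[:5]}")
    y = np.array([CASE if mapping[s] == case_label else CONTROL for s in subject_ids])
    return y, (control_label, case_label)


def write_dataset(dataset: ConnectomeDataset, path, fmt: str = "edge_table_csv") -> Path:
    """Write a dataset; ``fmt`` is ``edge_table_csv`` or ``square_csv``."""
    path = Path(path)
    if fmt == "edge_table_csv":
        path.parent.mkdir(parents=True, exist_ok=True)
        dataset.to_edge_table().to_csv(path, index=False, float_format="%.17g")
    elif fmt == "square_csv":
        if dataset.n_edges != dataset.edge_index.n_edges:
            raise ValueError("square_csv requires a full (unfiltered) edge set")
        path.mkdir(parents=True, exist_ok=True)
        names = list(dataset.edge_index.region_names)
        for row, sid in enumerate(dataset.subject_ids):
            m = devectorize(dataset.X[row], dataset.edge_index)
            pd.DataFrame(m, columns=names).to_csv(
                path / f"{sid}.csv", index=False, float_format="%.17g"
            )
        labels = {
            s: dataset.group_names[dataset.labels[r]]
            for r, s in enumerate(dataset.subject_ids)
        }
        (path / "labels.json").write_text(json.dumps(labels, indent=1))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def read_dataset(
    path,
    fmt: str = "edge_table_csv",
    band: str | None = None,
    edge_index: EdgeIndex | None = None,
    labels: dict | None = None,
    case_label: str = "PTSD",
) -> ConnectomeDataset:
    """Read a dataset written by :func:`write_dataset`.

    For ``square_csv``, ``path`` is the directory and ``band`` must be given
    (the matrix files carry no band information); labels default to the
    ``labels.json`` sidecar. For ``edge_table_csv``, the table's own columns
    supply everything; ``band`` selects one band if the table holds several.
    """
    path = Path(path)
    if fmt == "square_csv":
        if band is None:
            raise ValueError("square_csv input requires an explicit band name")
        if labels is None:
            labels = json.loads((path / "labels.json").read_text())
        subject_ids = sorted(labels)
        mats = []
        for sid in subject_ids:
            f = path / f"{sid}.csv"
            if not f.exists():
                raise FileNotFoundError(f"missing matrix file for subject {sid!r}: {f}")
            df = pd.read_csv(f)
            if edge_index is None:
                edge_index = EdgeIndex(df.columns)
            elif tuple(df.columns) != edge_index.region_names:
                raise ValueError(f"region names in {f} do not match the edge index")
            mats.append(vectorize_matrix(df.to_numpy(), edge_index))
        y, group_names = _labels_from_mapping(subject_ids, labels, case_label)
        return ConnectomeDataset(
            subject_ids=subject_ids,
            labels=y,
            band=band,
            X=np.vstack(mats),
            edge_index=edge_index,
            group_names=group_names,
        )

    if fmt == "edge_table_csv":
        df = pd.read_csv(path)
        required = {"subject_id", "group", "band", "region_a", "region_b", "wpli"}
        if not required <= set(df.columns):
            raise ValueError(f"edge table missing columns {sorted(required - set(df.columns))}")
        bands = df["band"].unique()
        if band is None:
            if len(bands) != 1:
                raise ValueError(f"table holds bands {list(bands)}; pass band=...")
            band = str(bands[0])
        df = df[df["band"] == band]
        if df.empty:
            raise ValueError(f"band {band!r} not present in table")
        if edge_index is None:
            edge_index = EdgeIndex(sorted(set(df["region_a"]) | set(df["region_b"])))
        eids = np.array(
            [edge_index.edge_id_by_name(a, b) for a, b in zip(df["region_a"], df["region_b"])]
        )
        sub = df["subject_id"].astype(str).to_numpy()
        subject_ids = sorted(set(sub))
        kept_edges = np.array(sorted(set(eids.tolist())), dtype=int)
        col = {int(e): c for c, e in enumerate(kept_edges)}
        row = {s: r for r, s in enumerate(subject_ids)}
        X = np.full((len(subject_ids), len(kept_edges)), np.nan)
        X[[row[s] for s in sub], [col[int(e)] for e in eids]] = df["wpli"].to_numpy()
        if np.isnan(X).any():
            bad_rows = sorted({subject_ids[r] for r in np.nonzero(np.isnan(X).any(axis=1))[0]})
            raise ValueError(f"incomplete edge table: subjects missing edges: {bad_rows[:5]}")
        mapping = labels or dict(zip(sub, df["group"].astype(str)))
        y, group_names = _labels_from_mapping(subject_ids, mapping, case_label)
        return ConnectomeDataset(
            subject_ids=subject_ids,
            labels=y,
            band=band,
            X=X,
            edge_index=edge_index,
            edge_ids=kept_edges,
            group_names=group_names,
        )

    raise ValueError(f"unknown format {fmt!r}")
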