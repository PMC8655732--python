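"""Readers and writers for the package's file dialects.

All formats are plain text except the optional packed-binary feature
matrix (little-endian float64, C row-major), which carries a JSON sidecar
stating shape, dtype and layout.  Text tables are tab-delimited with a
header row; the group-index file additionally documents the grid layout in
``# grid`` header comments so a fixture is self-describing.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .design import (
    FEATURE_TYPES,
    GroupedDesign,
    InstitutionShard,
    PatchGroup,
    SurfaceGrid,
)

__all__ = [
    "write_matrix",
    "read_matrix",
    "write_group_index",
    "read_group_index",
    "write_series",
    "read_series",
    "write_fixture",
    "read_fixture",
    "ParseError",
    "ValidationError",
]


class ParseError(ValueError):
    """A file does not conform to its dialect; names the offending line."""


class ValidationError(ValueError):
    """Files parse individually but are mutually inconsistent."""


# -- feature matrix ----------------------------------------------------------


def write_matrix(X: np.ndarray, path, fmt: str = "binary") -> list[Path]:
    """Write the subjects-by-features matrix as text or packed binary."""
    path = Path(path)
    X = np.ascontiguousarray(np.asarray(X, dtype=np.float64))
    if fmt == "binary":
        bin_path = path.with_suffix(".bin")
        X.tofile(bin_path)
        sidecar = path.with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {
                    "shape": list(X.shape),
                    "dtype": "<f8",
                    "layout": "C",
                    "byte_order": "little-endian",
                }
            )
            + "\n"
        )
        return [bin_path, sidecar]
    if fmt == "text":
        txt_path = path.with_suffix(".tsv")
        cols = [f"f{j:06d}" for j in range(X.shape[1])]
        df = pd.DataFrame(X, columns=cols)
        df.insert(0, "subject_id", [f"s{i:05d}" for i in range(X.shape[0])])
        df.to_csv(txt_path, sep="\t", index=False, float_format="%.17g")
        return [txt_path]
    raise ValueError(f"unknown matrix format {fmt!r}")


def read_matrix(path) -> np.ndarray:
    path = Path(path)
    if path.suffix == ".bin" or (path.suffix == "" and path.with_suffix(".bin").exists()):
        bin_path = path if path.suffix == ".bin" else path.with_suffix(".bin")
        sidecar = bin_path.with_suffix(".json")
        if not sidecar.exists():
            raise ParseError(f"missing sidecar {sidecar} for binary matrix")
        meta = json.loads(sidecar.read_text())
        X = np.fromfile(bin_path, dtype=np.dtype(meta["dtype"]))
        expected = int(np.prod(meta["shape"]))
        if X.size != expected:
            raise ParseError(
                f"{bin_path}: {X.size} values but sidecar declares shape {meta['shape']}"
            )
        return X.reshape(meta["shape"]).astype(np.float64)
    if path.suffix == ".tsv":
        df = pd.read_csv(path, sep="\t")
        if df.columns[0] != "subject_id":
            raise ParseError(f"{path}: first column must be subject_id")
        vals = df.drop(columns="subject_id").to_numpy(dtype=np.float64)
        return vals
    raise ParseError(f"{path}: unrecognized matrix file extension")


# -- group index -------------------------------------------------------------

GROUP_HEADER = (
    "# fedmorph group index. Vertex indices are 0-based row-major on each\n"
    "# rows x cols grid; feature columns are group-major in ascending\n"
    "# group_id, vertices row-major within each patch.\n"
)


def write_group_index(design: GroupedDesign, path) -> Path:
    path = Path(path)
    grids = design.grids
    fi = design.feature_index
    wmap = {g.group_id: g.weight for g in design.groups}
    lines = [GROUP_HEADER.rstrip("\n")]
    for grid in grids:
        lines.append(f"# grid {grid.hemisphere} {grid.rows} {grid.cols}")
    lines.append("feature_id\tgroup_id\themisphere\trow\tcol\tfeature_type\tweight")
    for j in range(len(fi)):
        h = grids[fi["hemisphere_idx"][j]]
        v = int(fi["vertex"][j])
        gid = int(fi["group_id"][j])
        lines.append(
            f"f{j:06d}\t{gid}\t{h.hemisphere}\t{v // h.cols}\t{v % h.cols}\t"
            f"{FEATURE_TYPES[fi['feature_type_idx'][j]]}\t{wmap[gid]:.17g}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def read_group_index(path):
    """Parse a group-index file -> (groups, feature_index, grids)."""
    path = Path(path)
    grids: list[SurfaceGrid] = []
    rows = []
    header_seen = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if parts[:1] == ["grid"]:
                    if len(parts) != 4:
                        raise ParseError(f"{path}:{lineno}: malformed grid header")
                    grids.append(
                        SurfaceGrid(int(parts[2]), int(parts[3]), parts[1])
                    )
                continue
            if not header_seen:
                if line.split("\t")[0] != "feature_id":
                    raise ParseError(f"{path}:{lineno}: expected column header")
                header_seen = True
                continue
            parts = line.split("\t")
            if len(parts) != 7:
                raise ParseError(
                    f"{path}:{lineno}: expected 7 fields, found {len(parts)}"
                )
            try:
                rows.append(
                    (
                        parts[0],
                        int(parts[1]),
                        parts[2],
                        int(parts[3]),
                        int(parts[4]),
                        parts[5],
                        float(parts[6]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    if not grids:
        raise ParseError(f"{path}: no '# grid' header lines")
    if not rows:
        raise ParseError(f"{path}: no feature rows")

    hemi_idx = {g.hemisphere: i for i, g in enumerate(grids)}
    p = len(rows)
    feature_index = np.zeros(
        p,
        dtype=[
            ("hemisphere_idx", "i4"),
            ("vertex", "i4"),
            ("feature_type_idx", "i4"),
            ("group_id", "i4"),
        ],
    )
    per_group: dict[int, dict] = {}
    for j, (fid, gid, hemi, r, c, ftype, w) in enumerate(rows):
        if hemi not in hemi_idx:
            raise ParseError(f"{path}: hemisphere {hemi!r} has no grid header")
        grid = grids[hemi_idx[hemi]]
        v = grid.vertex_id(r, c)
        feature_index[j] = (hemi_idx[hemi], v, FEATURE_TYPES.index(ftype), gid)
        info = per_group.setdefault(
            gid, {"hemisphere": hemi, "feature_type": ftype, "weight": w, "vertices": []}
        )
        info["vertices"].append(v)
    groups = [
        PatchGroup(
            group_id=gid,
            hemisphere=info["hemisphere"],
            feature_type=info["feature_type"],
            vertex_ids=tuple(info["vertices"]),
            weight=info["weight"],
        )
        for gid, info in sorted(per_group.items())
    ]
    return groups, feature_index, tuple(grids)


# -- simple two-column series ------------------------------------------------


def write_series(values, path, value_name: str = "value", ids=None) -> Path:
    path = Path(path)
    values = np.asarray(values)
    if ids is None:
        ids = [f"s{i:05d}" for i in range(len(values))]
    with open(path, "w") as fh:
        fh.write(f"subject_id\t{value_name}\n")
        for sid, v in zip(ids, values):
            if np.issubdtype(values.dtype, np.integer):
                fh.write(f"{sid}\t{int(v)}\n")
            else:
                fh.write(f"{sid}\t{v:.17g}\n")
    return path


def read_series(path, dtype=float) -> tuple[list[str], np.ndarray]:
    path = Path(path)
    ids: list[str] = []
    vals: list = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if lineno == 1:
                if len(line.split("\t")) != 2:
                    raise ParseError(f"{path}:{lineno}: expected two-column header")
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 fields, found {len(parts)}"
                )
            try:
                vals.append(dtype(parts[1]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            ids.append(parts[0])
    return ids, np.asarray(vals)


# -- fixture directories -----------------------------------------------------


def write_fixture(design, shards, truth, directory, matrix_format="binary") -> dict:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files: dict[str, object] = {}
    files["matrix"] = write_matrix(design.X, directory / "matrix", matrix_format)
    files["groups"] = write_group_index(design, directory / "groups.tsv")
    files["response"] = write_series(design.y, directory / "response.tsv")
    site_of_row = np.empty(design.n_subjects, dtype=np.int64)
    for s in shards:
        site_of_row[s.row_ids] = s.site_id
    files["sites"] = write_series(
        site_of_row, directory / "sites.tsv", value_name="site_id"
    )
    if truth is not None:
        lines = ["feature_id\tgroup_id\tcoefficient"]
        gid_of_col = design.feature_index["group_id"]
        for j in np.flatnonzero(np.isin(gid_of_col, truth.support)):
            lines.append(
                f"f{j:06d}\t{gid_of_col[j]}\t{truth.beta_true[j]:.17g}"
            )
        truth_path = directory / "truth.tsv"
        truth_path.write_text("\n".join(lines) + "\n")
        files["truth"] = truth_path
    return files


def read_fixture(directory):
    """Load a fixture directory -> (design, shards, truth_or_None).

    Validates that the group index exactly partitions the matrix columns
    before anything downstream can run.
    """
    from .simulate import SyntheticTruth

    directory = Path(directory)
    groups, feature_index, grids = read_group_index(directory / "groups.tsv")
    if (directory / "matrix.bin").exists():
        X = read_matrix(directory / "matrix.bin")
    else:
        X = read_matrix(directory / "matrix.tsv")
    _, y = read_series(directory / "response.tsv")
    if X.shape[1] != len(feature_index):
        raise ValidationError(
            f"matrix has {X.shape[1]} columns but group index describes "
            f"{len(feature_index)}"
        )
    if X.shape[0] != len(y):
        raise ValidationError(
            f"matrix has {X.shape[0]} rows but response has {len(y)}"
        )
    design = GroupedDesign(
        X=X, y=y, groups=groups, feature_index=feature_index, grids=grids
    )
    _, site_of_row = read_series(directory / "sites.tsv", dtype=int)
    if len(site_of_row) != design.n_subjects:
        raise ValidationError("site assignment length does not match matrix rows")
    shards = [
        InstitutionShard(
            site_id=int(sid),
            X_i=design.X[site_of_row == sid],
            y_i=design.y[site_of_row == sid],
            row_ids=np.flatnonzero(site_of_row == sid),
        )
        for sid in np.unique(site_of_row)
    ]
    truth = None
    truth_path = directory / "truth.tsv"
    if truth_path.exists():
        beta_true = np.zeros(design.n_features)
        support = set()
        with open(truth_path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or lineno == 1:
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise ParseError(
                        f"{truth_path}:{lineno}: expected 3 fields, found {len(parts)}"
                    )
                j = int(parts[0].lstrip("f"))
                support.add(int(parts[1]))
                beta_true[j] = float(parts[2])
        truth = SyntheticTruth(
            support=tuple(sorted(support)),
            beta_true=beta_true,
            noise_sd=float("nan"),
            smoothness=float("nan"),
            seed=-1,
        )
    return design, shards, truth
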