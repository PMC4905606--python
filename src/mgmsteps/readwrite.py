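"""Plain-text readers and writers: mixed data tables, edge lists, parameter
containers and instability reports.

All formats are delimited text (tab-separated) so fixtures diff cleanly in
version control.  Mixed tables carry a second header line declaring each
column ``continuous`` or ``categorical``; categorical cells hold level
labels, mapped to indices in first-appearance order (the mapping travels
with the dataset and is serialized with fitted parameters).  Level indices
are 1-based in external files; the in-memory representation is 0-based.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import MGMParameters, MixedDataset, adjacency_from_parameters

__all__ = [
    "write_mixed_table", "read_mixed_table",
    "write_edge_list", "read_edge_list", "edge_records",
    "write_parameters", "read_parameters",
    "write_instability_report",
]

_TYPE_PREFIX = "#types"


def write_mixed_table(data: MixedDataset, path) -> None:
    """Write a dataset as a tab-separated table with a type-declaration line."""
    path = Path(path)
    names = data.names
    types = ["continuous"] * data.p + ["categorical"] * data.q
    with path.open("w") as fh:
        fh.write("\t".join(names) + "\n")
        fh.write(_TYPE_PREFIX + "\t" + "\t".join(types) + "\n")
        for i in range(data.n):
            row = [repr(float(v)) for v in data.X[i]]
            row += [data.level_labels[j][data.Y[i, j]] for j in range(data.q)]
            fh.write("\t".join(row) + "\n")


def read_mixed_table(path) -> MixedDataset:
    """Read a mixed table written by :func:`write_mixed_table`.

    Continuous columns parse as floats; categorical labels are mapped to
    indices in order of first appearance.  Missing or unparseable cells
    raise with the offending row and column named.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        type_line = fh.readline().rstrip("\n").split("\t")
        if not type_line or type_line[0] != _TYPE_PREFIX:
            raise ValueError(f"{path}: second line must start with {_TYPE_PREFIX}")
        types = type_line[1:]
        if len(types) != len(header):
            raise ValueError(f"{path}: type declaration does not cover all columns")
        bad = [t for t in types if t not in ("continuous", "categorical")]
        if bad:
            raise ValueError(f"{path}: unknown column type {bad[0]!r}")
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    ncol = len(header)
    for i, row in enumerate(rows):
        if len(row) != ncol:
            raise ValueError(f"{path}: row {i + 3} has {len(row)} cells, expected {ncol}")
        for c, cell in enumerate(row):
            if cell == "":
                raise ValueError(
                    f"{path}: missing cell at row {i + 3}, column {header[c]!r}")

    cont_cols = [c for c, t in enumerate(types) if t == "continuous"]
    cat_cols = [c for c, t in enumerate(types) if t == "categorical"]
    n = len(rows)
    X = np.empty((n, len(cont_cols)))
    for k, c in enumerate(cont_cols):
        for i, row in enumerate(rows):
            try:
                X[i, k] = float(row[c])
            except ValueError:
                raise ValueError(
                    f"{path}: unparseable value {row[c]!r} at row {i + 3}, "
                    f"column {header[c]!r}") from None
    Y = np.empty((n, len(cat_cols)), dtype=int)
    labels = []
    for k, c in enumerate(cat_cols):
        seen: dict = {}
        for i, row in enumerate(rows):
            lab = row[c]
            if lab not in seen:
                seen[lab] = len(seen)
            Y[i, k] = seen[lab]
        if len(seen) < 2:
            import warnings
            warnings.warn(f"{path}: categorical column {header[c]!r} has a "
                          "single observed level", RuntimeWarning)
            # pad so the level count stays valid
            seen[f"_unobserved_{len(seen)}"] = len(seen)
        labels.append(list(seen))
    levels = tuple(len(ll) for ll in labels)
    return MixedDataset(X, Y, levels,
                        [header[c] for c in cont_cols],
                        [header[c] for c in cat_cols], labels)


# ---------------------------------------------------------------------------
# edge lists
# ---------------------------------------------------------------------------


def edge_records(params: MGMParameters, names, threshold: float = 0.0) -> list:
    """One record per present edge: (source, target, edge_type, weight) where
    weight is the maximum-magnitude parameter of the block (signed for cc)."""
    p, q = params.p, params.q
    if len(names) != p + q:
        raise ValueError("need one name per variable")
    A = adjacency_from_parameters(params, threshold)
    offs = params.offsets
    records = []
    for a in range(p + q):
        for b in range(a + 1, p + q):
            if not A[a, b]:
                continue
            if b < p:
                w = float(params.beta[a, b])
                et = "cc"
            elif a < p:
                blk = params.rho[a, offs[b - p]:offs[b - p + 1]]
                w = float(blk[np.argmax(np.abs(blk))])
                et = "cd"
            else:
                blk = params.phi_block(a - p, b - p)
                w = float(blk.ravel()[np.argmax(np.abs(blk))])
                et = "dd"
            records.append((names[a], names[b], et, w))
    return records


def write_edge_list(params: MGMParameters, names, path,
                    threshold: float = 0.0) -> None:
    with Path(path).open("w") as fh:
        fh.write("source\ttarget\tedge_type\tweight\n")
        for rec in edge_records(params, names, threshold):
            fh.write(f"{rec[0]}\t{rec[1]}\t{rec[2]}\t{rec[3]!r}\n")


def read_edge_list(path, names) -> np.ndarray:
    """Read an edge list back into a symmetric boolean adjacency over the
    given variable-name order."""
    idx = {nm: i for i, nm in enumerate(names)}
    P = len(names)
    A = np.zeros((P, P), dtype=bool)
    df = pd.read_csv(path, sep="\t")
    for _, row in df.iterrows():
        try:
            a, b = idx[row["source"]], idx[row["target"]]
        except KeyError as e:
            raise ValueError(f"unknown variable name {e.args[0]!r} in {path}")
        A[a, b] = A[b, a] = True
    return A


# ---------------------------------------------------------------------------
# parameter container
# ---------------------------------------------------------------------------


def write_parameters(params: MGMParameters, path, cont_names=None,
                     cat_names=None, level_labels=None) -> None:
    """Serialize fitted parameters to JSON keyed by variable-name pairs.

    Floats are written with full shortest-repr precision, so a read/write
    round trip is bit-exact.
    """
    p, q = params.p, params.q
    cont_names = list(cont_names) if cont_names else [f"x{s+1}" for s in range(p)]
    cat_names = list(cat_names) if cat_names else [f"y{j+1}" for j in range(q)]
    level_labels = level_labels or [[str(k + 1) for k in range(L)]
                                    for L in params.levels]
    obj = {
        "continuous": cont_names,
        "categorical": cat_names,
        "levels": {cat_names[j]: list(level_labels[j]) for j in range(q)},
        "beta": params.beta.tolist(),
        "alpha": params.alpha.tolist(),
        "rho": {f"{cont_names[s]}|{cat_names[j]}": params.rho_block(s, j).tolist()
                for s in range(p) for j in range(q)},
        "phi": {f"{cat_names[r]}|{cat_names[j]}": params.phi_block(r, j).tolist()
                for r in range(q) for j in range(r, q)},
        "x_mean": None if params.x_mean is None else params.x_mean.tolist(),
        "x_sd": None if params.x_sd is None else params.x_sd.tolist(),
        "fit_info": params.fit_info,
    }
    with Path(path).open("w") as fh:
        json.dump(obj, fh, indent=1)


def read_parameters(path) -> MGMParameters:
    with Path(path).open() as fh:
        obj = json.load(fh)
    cont = obj["continuous"]
    cat = obj["categorical"]
    levels = tuple(len(obj["levels"][nm]) for nm in cat)
    p, q = len(cont), len(cat)
    offs = np.concatenate([[0], np.cumsum(levels)]).astype(int)
    Q = int(offs[-1])
    rho = np.zeros((p, Q))
    for s in range(p):
        for j in range(q):
            rho[s, offs[j]:offs[j + 1]] = obj["rho"][f"{cont[s]}|{cat[j]}"]
    phi = np.zeros((Q, Q))
    for r in range(q):
        for j in range(r, q):
            blk = np.asarray(obj["phi"][f"{cat[r]}|{cat[j]}"])
            phi[offs[r]:offs[r + 1], offs[j]:offs[j + 1]] = blk
            phi[offs[j]:offs[j + 1], offs[r]:offs[r + 1]] = blk.T
    return MGMParameters(
        np.asarray(obj["beta"]), np.asarray(obj["alpha"]), rho, phi, levels,
        None if obj["x_mean"] is None else np.asarray(obj["x_mean"]),
        None if obj["x_sd"] is None else np.asarray(obj["x_sd"]),
        obj.get("fit_info", {}),
    )


def write_instability_report(profile, path) -> None:
    """Per-lambda, per-edge-type instability table as tab-separated text."""
    rows = []
    for i, lam in enumerate(profile.lambdas):
        row = {"lambda": lam}
        for et, d in profile.d_hat.items():
            row[f"d_hat_{et}"] = d[i]
            row[f"d_bar_{et}"] = profile.d_bar[et][i]
        row["mean_subsample_edges"] = float(profile.edge_counts[:, i].mean())
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
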