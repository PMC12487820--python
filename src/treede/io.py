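"""Plain-text and HDF5 interchange formats.

Conventions:

- trees are newick text files;
- count matrices are TSV with the feature ID in the first column and one
  column per sample (features are rows on disk; in memory the package works
  samples-first);
- inferential replicates are either a directory of per-replicate count
  TSVs named ``rep_0001.tsv``, ``rep_0002.tsv``, ... or a single HDF5 file
  with datasets ``counts`` (sample x feature x replicate), ``point``,
  ``features`` and ``samples`` — both dialects are auto-detected;
- the condition is a two-column TSV (sample, condition) without a header;
- run configuration is a flat ``key=value`` text file.
"""

from __future__ import annotations

import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .tree import ReplicateTensor, TranscriptTree, parse_newick, write_newick

logger = logging.getLogger("treede")


def read_tree(path) -> TranscriptTree:
    return parse_newick(Path(path).read_text())


def write_tree(tree: TranscriptTree, path) -> None:
    Path(path).write_text(write_newick(tree) + "\n")


def read_counts(path) -> pd.DataFrame:
    """Read a feature x sample TSV into a samples x features DataFrame."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValueError(f"no counts found in {path}")
    return df.T


def write_counts(counts: pd.DataFrame, path) -> None:
    """Write a samples x features DataFrame as a feature x sample TSV."""
    out = counts.T
    out.index.name = "feature"
    out.to_csv(path, sep="\t")


def read_condition(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "condition"],
                     dtype=str)
    if df["sample"].duplicated().any():
        raise ValueError(f"duplicate sample IDs in {path}")
    return df.set_index("sample")["condition"]


def write_condition(condition: pd.Series, path) -> None:
    condition.rename("condition").to_csv(path, sep="\t", header=False)


# ---------------------------------------------------------------------------
# replicate containers
# ---------------------------------------------------------------------------


def write_replicates_dir(tensor: ReplicateTensor, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for r in range(tensor.n_replicates):
        df = pd.DataFrame(
            tensor.counts[:, :, r],
            index=tensor.sample_ids,
            columns=tensor.feature_ids,
        )
        write_counts(df, path / f"rep_{r + 1:04d}.tsv")
    point = pd.DataFrame(tensor.point, index=tensor.sample_ids,
                         columns=tensor.feature_ids)
    write_counts(point, path / "point.tsv")


def read_replicates_dir(path) -> ReplicateTensor:
    path = Path(path)
    rep_files = sorted(path.glob("rep_*.tsv"))
    if not rep_files:
        raise ValueError(f"no rep_*.tsv files in {path}")
    mats = []
    first = read_counts(rep_files[0])
    for f in rep_files:
        df = read_counts(f)
        if list(df.index) != list(first.index) or list(df.columns) != list(first.columns):
            raise ValueError(f"replicate file {f} is inconsistent with {rep_files[0]}")
        mats.append(df.to_numpy(dtype=np.float64))
    counts = np.stack(mats, axis=2)
    point_file = path / "point.tsv"
    point = read_counts(point_file).to_numpy(dtype=np.float64) if point_file.exists() else None
    return ReplicateTensor.from_replicates(
        counts, list(first.columns), list(first.index), point=point
    )


def write_replicates_h5(tensor: ReplicateTensor, path) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("counts", data=tensor.counts, compression="gzip")
        h5.create_dataset("point", data=tensor.point, compression="gzip")
        str_dt = h5py.string_dtype()
        h5.create_dataset("features", data=np.array(tensor.feature_ids, dtype=object),
                          dtype=str_dt)
        h5.create_dataset("samples", data=np.array(tensor.sample_ids, dtype=object),
                          dtype=str_dt)


def read_replicates_h5(path) -> ReplicateTensor:
    with h5py.File(path, "r") as h5:
        counts = h5["counts"][...]
        point = h5["point"][...] if "point" in h5 else None
        features = [x.decode() if isinstance(x, bytes) else str(x)
                    for x in h5["features"][...]]
        samples = [x.decode() if isinstance(x, bytes) else str(x)
                   for x in h5["samples"][...]]
    return ReplicateTensor.from_replicates(counts, features, samples, point=point)


def read_replicates(path) -> ReplicateTensor:
    """Auto-detect the replicate container dialect and read it."""
    path = Path(path)
    if path.is_dir():
        return read_replicates_dir(path)
    return read_replicates_h5(path)


# ---------------------------------------------------------------------------
# flat config
# ---------------------------------------------------------------------------


def read_config(path) -> dict:
    """Parse a flat ``key=value`` file; '#' starts a comment."""
    out = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def check_samples_match(counts: pd.DataFrame, condition: pd.Series) -> pd.Series:
    """Cross-check sample IDs and return the condition aligned to the counts."""
    missing = [s for s in counts.index if s not in condition.index]
    extra = [s for s in condition.index if s not in counts.index]
    if missing or extra:
        raise ValueError(
            f"sample IDs disagree between counts and condition file "
            f"(missing from condition: {missing[:5]}; unknown: {extra[:5]})"
        )
    return condition.loc[counts.index]
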