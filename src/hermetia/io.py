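"""Readers and writers for the interchange formats.

Count tables travel in the mothur-shared-style dialect (``label  Group
numOtus  Otu0001 ...``, tab-separated) with a companion taxonomy TSV
(``OTU  Size  Taxonomy``) and a sample metadata TSV; trial observables are
plain CSV.  Sample identity is the join key everywhere — row order never
carries meaning.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from hermetia.community import AbundanceTable, DistanceMatrix

log = logging.getLogger(__name__)

__all__ = [
    "read_abundance_table",
    "write_shared",
    "write_taxonomy",
    "read_trial_tables",
    "write_distance_matrix",
    "read_distance_matrix",
    "write_results",
    "checksum_tree",
]


# ---------------------------------------------------------------------------
# shared-style count tables
# ---------------------------------------------------------------------------

def write_shared(table: AbundanceTable, path: "str | Path", label: str = "0.03") -> None:
    out = table.counts.copy()
    out.insert(0, "numOtus", len(table.taxon_ids))
    out.insert(0, "Group", out.index)
    out.insert(0, "label", label)
    out.to_csv(path, sep="\t", index=False)


def write_taxonomy(table: AbundanceTable, path: "str | Path") -> None:
    if table.taxonomy is None:
        raise ValueError("table has no taxonomy")
    frame = pd.DataFrame({
        "OTU": table.taxon_ids,
        "Size": table.counts.sum(axis=0).to_numpy(),
        "Taxonomy": table.taxonomy[table.taxon_ids].to_numpy(),
    })
    frame.to_csv(path, sep="\t", index=False)


def read_abundance_table(shared_path: "str | Path",
                         taxonomy_path: "str | Path | None" = None,
                         metadata_path: "str | Path | None" = None) -> AbundanceTable:
    """Parse shared + taxonomy + metadata files into an :class:`AbundanceTable`.

    Samples are intersected across files; samples present in the counts but
    missing from the metadata are dropped with a warning.  Non-integer or
    negative counts are hard errors naming the offending cell.
    """
    shared = pd.read_csv(shared_path, sep="\t")
    for col in ("Group", "numOtus"):
        if col not in shared.columns:
            raise ValueError(f"shared file missing column {col!r}")
    if shared["Group"].duplicated().any():
        dups = shared.loc[shared["Group"].duplicated(), "Group"].tolist()
        raise ValueError(f"duplicate sample ids: {dups}")
    otu_cols = [c for c in shared.columns if c not in ("label", "Group", "numOtus")]
    counts = shared.set_index("Group")[otu_cols]
    for col in otu_cols:
        vals = pd.to_numeric(counts[col], errors="coerce")
        if vals.isna().any():
            row = counts.index[vals.isna()][0]
            raise ValueError(f"non-numeric count at sample {row!r}, taxon {col!r}")
        if (vals % 1 != 0).any():
            row = counts.index[(vals % 1 != 0)][0]
            raise ValueError(f"non-integer count at sample {row!r}, taxon {col!r}")
        if (vals < 0).any():
            row = counts.index[vals < 0][0]
            raise ValueError(f"negative count at sample {row!r}, taxon {col!r}")
    counts = counts.astype(np.int64)

    taxonomy = None
    if taxonomy_path is not None:
        tax = pd.read_csv(taxonomy_path, sep="\t")
        taxonomy = tax.set_index("OTU")["Taxonomy"]
        missing = set(otu_cols) - set(taxonomy.index)
        if missing:
            raise ValueError(f"taxonomy missing taxa: {sorted(missing)[:5]}")
        taxonomy = taxonomy[otu_cols]

    metadata = None
    if metadata_path is not None:
        metadata = pd.read_csv(metadata_path, sep="\t", index_col=0)
        keep = counts.index.intersection(metadata.index)
        dropped = counts.index.difference(metadata.index)
        if len(dropped):
            log.warning("dropping %d samples missing from metadata: %s",
                        len(dropped), list(dropped))
        counts = counts.loc[keep]
        metadata = metadata.loc[keep]
    return AbundanceTable(counts, taxonomy, metadata)


# ---------------------------------------------------------------------------
# trial tables
# ---------------------------------------------------------------------------

_OBS_COLUMNS = ["box", "diet", "day", "n_alive", "n_pupae",
                "mean_fresh_mg", "mean_dry_mg"]
_FEED_COLUMNS = ["box", "day", "offered_fresh_mg", "dry_frac"]
_RES_COLUMNS = ["box", "day", "residue_dry_mg"]


def read_trial_tables(observations_path: "str | Path", feeding_path: "str | Path",
                      residue_path: "str | Path",
                      ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read and validate the three trial CSVs, sorting rows by box and day."""
    obs = pd.read_csv(observations_path)
    feed = pd.read_csv(feeding_path)
    res = pd.read_csv(residue_path)
    for frame, needed, name in ((obs, _OBS_COLUMNS, "observations"),
                                (feed, _FEED_COLUMNS, "feeding log"),
                                (res, _RES_COLUMNS, "residues")):
        missing = [c for c in needed if c not in frame.columns]
        if missing:
            raise ValueError(f"{name} missing columns: {missing}")
    if ((feed["dry_frac"] <= 0) | (feed["dry_frac"] > 1)).any():
        raise ValueError("feeding log dry_frac outside (0, 1]")
    if (obs["mean_dry_mg"] > obs["mean_fresh_mg"] + 1e-9).any():
        raise ValueError("dry mass exceeds fresh mass")
    for frame, name in ((obs, "observations"), (feed, "feeding log")):
        unsorted = frame.groupby("box")["day"].apply(lambda s: not s.is_monotonic_increasing)
        if unsorted.any():
            log.warning("%s: out-of-order days in boxes %s; sorting",
                        name, list(unsorted[unsorted].index))
    obs = obs.sort_values(["box", "day"]).reset_index(drop=True)
    feed = feed.sort_values(["box", "day"]).reset_index(drop=True)
    return obs, feed, res


# ---------------------------------------------------------------------------
# matrices and results
# ---------------------------------------------------------------------------

def write_distance_matrix(dist: DistanceMatrix, path: "str | Path") -> None:
    dist.to_frame().to_csv(path, sep="\t")


def read_distance_matrix(path: "str | Path") -> DistanceMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(frame.to_numpy(dtype=float), list(frame.index))


def write_results(outputs: dict[str, pd.DataFrame], out_dir: "str | Path",
                  seed: int | None = None, config: dict | None = None,
                  overwrite: bool = False) -> Path:
    """Write stage output tables as TSV plus a run manifest.

    ``outputs`` maps a stage name (used as the file stem) to its table.
    Existing files are a collision error unless ``overwrite`` is set.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, frame in outputs.items():
        path = out / f"{name}.tsv"
        if path.exists() and not overwrite:
            raise FileExistsError(f"{path} exists; pass overwrite=True")
        frame.to_csv(path, sep="\t")
    manifest = {
        "seed": seed,
        "tables": sorted(f"{n}.tsv" for n in outputs),
        "config": config or {},
    }
    try:
        from hermetia import __version__
        manifest["version"] = __version__
    except Exception:
        pass
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out


def checksum_tree(directory: "str | Path") -> dict[str, str]:
    """SHA-256 of every file under a directory (determinism checks)."""
    root = Path(directory)
    out = {}
    for path in sorted(root.rglob("*")):
        if path.is_file():
            out[str(path.relative_to(root))] = hashlib.sha256(path.read_bytes()).hexdigest()
    return out
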