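"""Readers/writers for the on-disk formats shared by the CLI and library.

BED inputs are 0-based half-open and converted to the internal 1-based
inclusive convention at the boundary; everything written back out follows
the same rule.  Encodings are archived to HDF5 with one group per site.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .annotation import GenomicInterval
from .consistency import TechniqueSet

logger = logging.getLogger(__name__)

__all__ = [
    "read_bed_sites",
    "read_bed_records",
    "write_bed_sites",
    "read_technique_set",
    "write_encodings_h5",
    "read_encodings_h5",
    "write_provenance",
]


def read_bed_sites(path: str) -> list[GenomicInterval]:
    """BED6 -> 1-based inclusive intervals; strand column is required."""
    sites = []
    skipped = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6 or parts[5] not in ("+", "-"):
                skipped += 1
                continue
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            sites.append(GenomicInterval(chrom, start + 1, end, parts[5]))
    logger.info("read %d sites from %s (%d records skipped)",
                len(sites), path, skipped)
    return sites


def read_bed_records(path: str) -> list[tuple[GenomicInterval, str, str]]:
    """BED6 rows as (interval, name, score) with coordinates converted."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6 or parts[5] not in ("+", "-"):
                continue
            iv = GenomicInterval(parts[0], int(parts[1]) + 1, int(parts[2]),
                                 parts[5])
            out.append((iv, parts[3], parts[4]))
    return out


def write_bed_sites(path: str, sites: Iterable[GenomicInterval],
                    names: Optional[Sequence[str]] = None,
                    scores: Optional[Sequence] = None) -> None:
    sites = list(sites)
    names = names or ["." for _ in sites]
    scores = scores if scores is not None else [0 for _ in sites]
    with open(path, "w") as fh:
        for s, n, sc in zip(sites, names, scores):
            fh.write(f"{s.chrom}\t{s.start - 1}\t{s.end}\t{n}\t{sc}\t{s.strand}\n")


def read_technique_set(path: str, name: Optional[str] = None) -> TechniqueSet:
    """One BED file of single-nucleotide sites -> a named TechniqueSet."""
    sites = read_bed_sites(path)
    keys = [(s.chrom, s.start, s.strand) for s in sites]
    return TechniqueSet(name or Path(path).stem, keys)


def write_encodings_h5(path: str, records: Sequence[dict],
                       params: Optional[dict] = None) -> None:
    """One HDF5 group per site: matrices, tx ids, label, encoder params."""
    import h5py

    with h5py.File(path, "w") as fh:
        if params:
            for k, v in params.items():
                fh.attrs[k] = v
        for i, rec in enumerate(records):
            grp = fh.create_group(f"site{i:06d}")
            for key, val in rec.items():
                if isinstance(val, np.ndarray):
                    grp.create_dataset(key, data=val)
                elif isinstance(val, (list, tuple)) and val \
                        and isinstance(val[0], str):
                    grp.create_dataset(
                        key, data=np.array(val, dtype=h5py.string_dtype())
                    )
                elif val is not None:
                    grp.attrs[key] = val


def read_encodings_h5(path: str) -> tuple[list[dict], dict]:
    import h5py

    records = []
    with h5py.File(path, "r") as fh:
        params = dict(fh.attrs)
        for key in sorted(fh.keys()):
            grp = fh[key]
            rec = dict(grp.attrs)
            for dkey in grp.keys():
                arr = grp[dkey][()]
                if arr.dtype.kind in ("S", "O"):
                    rec[dkey] = [
                        x.decode() if isinstance(x, bytes) else str(x)
                        for x in arr
                    ]
                else:
                    rec[dkey] = arr
            records.append(rec)
    return records, params


def write_provenance(out_dir: str, config: dict, seed: Optional[int]) -> None:
    """Record the run configuration and versions beside the outputs."""
    import sys

    from . import __version__

    payload = {
        "geotx_version": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "seed": seed,
        "config": {k: _jsonable(v) for k, v in config.items()},
    }
    Path(out_dir).mkdir(parents=True, exist_ok=True)
    with open(Path(out_dir) / "provenance.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def _jsonable(v):
    if isinstance(v, (np.integer, np.floating)):
        return v.item()
    if isinstance(v, (list, tuple)):
        return [_jsonable(x) for x in v]
    if isinstance(v, Path):
        return str(v)
    return v
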