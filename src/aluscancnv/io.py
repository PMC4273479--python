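"""Readers and writers for the tab-delimited interchange formats.

All tables are plain TSV with a header line; coordinates are BED-style
0-based half-open.  Depth tables are (chrom, start, end, depth[, gc]);
templates add a JSON sidecar with n_samples and total_reads.  Float output
uses a fixed ``%.6g``-style format so identical inputs always serialize
byte-identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .template import ReferenceTemplate
from .windows import DepthProfile

__all__ = [
    "read_chrom_sizes",
    "read_bed_intervals",
    "read_depth_table",
    "write_depth_table",
    "read_template",
    "write_template",
    "write_table",
    "read_labels",
    "read_feature_matrix",
]

_FLOAT_FMT = "%.6g"


def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column TSV: chromosome name, length."""
    out: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        name, length = line.split("\t")[:2]
        out[name] = int(length)
    return out


def read_bed_intervals(path):
    """Yield (chrom, start, end) from a BED3+ file."""
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        yield f[0], int(f[1]), int(f[2])


def _fmt_depth(d: float) -> str:
    return str(int(d)) if float(d).is_integer() else _FLOAT_FMT % d


def write_depth_table(profile: DepthProfile, path) -> None:
    win = profile.windows
    with open(path, "w") as fh:
        cols = "chrom\tstart\tend\tdepth"
        has_gc = "gc" in win.columns
        fh.write(cols + ("\tgc" if has_gc else "") + "\n")
        gc = win["gc"].to_numpy() if has_gc else None
        for i, (c, s, e) in enumerate(zip(win["chrom"], win["start"], win["end"])):
            row = f"{c}\t{s}\t{e}\t{_fmt_depth(profile.depth[i])}"
            if has_gc:
                g = gc[i]
                row += "\t" + ("NA" if np.isnan(g) else _FLOAT_FMT % g)
            fh.write(row + "\n")


def read_depth_table(path, sample_id: str | None = None) -> DepthProfile:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    windows = df[["chrom", "start", "end"] + (["gc"] if "gc" in df.columns else [])]
    return DepthProfile(
        sample_id=sample_id or Path(path).stem,
        windows=windows.reset_index(drop=True),
        depth=df["depth"].to_numpy(dtype=float),
    )


def write_template(template: ReferenceTemplate, path) -> None:
    prof = DepthProfile("template", template.windows, template.pooled_depth)
    write_depth_table(prof, path)
    meta = {
        "n_samples": template.n_samples,
        "total_reads": template.total_reads,
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, sort_keys=True) + "\n")


def read_template(path) -> ReferenceTemplate:
    prof = read_depth_table(path)
    meta_path = Path(str(path) + ".meta.json")
    n_samples = 1
    if meta_path.exists():
        n_samples = int(json.loads(meta_path.read_text()).get("n_samples", 1))
    return ReferenceTemplate(
        windows=prof.windows, pooled_depth=prof.depth, n_samples=n_samples
    )


def write_table(df: pd.DataFrame, path) -> None:
    """Deterministic TSV writer for call/segment/result tables."""
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_labels(path) -> pd.Series:
    """Two-column TSV sample -> class label."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "label"])
    return df.set_index("sample")["label"]


def read_feature_matrix(path) -> pd.DataFrame:
    """Samples × features binary matrix; first column holds sample ids."""
    return pd.read_csv(path, sep="\t", index_col=0)
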