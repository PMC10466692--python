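"""Readers and writers for the on-disk formats.

TSV for bin tables, fragment profiles, count fixtures and reports; BED
(0-based half-open) for CNV calls; JSON for simulation truth and report
summaries; YAML for run configuration.  Packaged fixture tables live under
``cfscreen/fixtures`` and are accessed through :func:`fixture_path`.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cnv import CnvCall, SegmentationConfig
from .fetal_fraction import FragmentProfile
from .pipeline import RunConfig
from .simulate import SimTruth
from .windows import BinTable

__all__ = [
    "read_bintable", "write_bintable",
    "read_fragment_profile", "write_fragment_profile",
    "read_fixture", "fixture_path", "list_fixtures",
    "write_bed", "read_truth", "write_truth",
    "load_config", "save_config", "log_run_context",
]

logger = logging.getLogger("cfscreen")

_BINTABLE_NUMERIC = ("start", "end", "gc", "raw_count")


def _read_tsv(path) -> pd.DataFrame:
    # engine='python' + explicit str dtype lets us report malformed cells
    # with their row index; CRLF and LF both parse.
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def _numeric(df: pd.DataFrame, col: str, path) -> np.ndarray:
    try:
        return pd.to_numeric(df[col], errors="raise").to_numpy()
    except (ValueError, TypeError):
        bad = pd.to_numeric(df[col], errors="coerce")
        row = int(np.argmax(bad.isna().to_numpy()))
        raise ValueError(
            f"{path}: malformed numeric value in column {col!r} at row {row}"
        ) from None


def read_bintable(path) -> BinTable:
    df = _read_tsv(path)
    required = ["chrom", "start", "end", "gc", "raw_count"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {', '.join(missing)}")
    for c in df.columns:
        if c != "chrom":
            df[c] = _numeric(df, c, path)
    return BinTable.from_frame(df)


def write_bintable(table: BinTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_fragment_profile(path) -> FragmentProfile:
    df = _read_tsv(path)
    required = ["chrom", "start", "end", "n_short_100_150", "n_total"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {', '.join(missing)}")
    for c in df.columns:
        if c != "chrom":
            df[c] = _numeric(df, c, path)
    return FragmentProfile.from_frame(df)


def write_fragment_profile(profile: FragmentProfile, path) -> None:
    profile.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")


# -- count fixtures ---------------------------------------------------------

_FIXTURE_COUNT_COLS = (
    "n_screen_positive", "n_confirmed", "n_diagnostic_positive", "n_detected",
    "n_maternal_origin", "n_larger_than_cma",
)
_FIXTURE_KNOWN = ("label", "stratum", "printed_pct") + _FIXTURE_COUNT_COLS


def read_fixture(path) -> list[dict]:
    """Load a transcribed-count fixture; validates schema and counts."""
    df = _read_tsv(path)
    if "label" not in df.columns or df.empty:
        raise ValueError(f"{path}: fixture needs a 'label' column and rows")
    extra = [c for c in df.columns if c not in _FIXTURE_KNOWN]
    if extra:
        warnings.warn(
            f"{path}: ignoring unknown fixture column(s) {', '.join(extra)}",
            stacklevel=2,
        )
        df = df.drop(columns=extra)
    rows = []
    for i, rec in enumerate(df.to_dict("records")):
        out = {"label": rec["label"]}
        for col in _FIXTURE_COUNT_COLS:
            val = rec.get(col, "")
            if val == "":
                continue
            try:
                n = int(val)
            except ValueError:
                raise ValueError(
                    f"{path}: non-integer count {val!r} in row {i}"
                ) from None
            if n < 0:
                raise ValueError(f"{path}: negative count in row {i}")
            out[col] = n
        if "printed_pct" in rec and rec["printed_pct"] != "":
            out["printed_pct"] = float(rec["printed_pct"])
        if rec.get("stratum"):
            out["stratum"] = rec["stratum"]
        rows.append(out)
    return rows


def fixture_path(name: str) -> Path:
    p = resources.files("cfscreen") / "fixtures" / name
    with resources.as_file(p) as fp:
        return Path(fp)


def list_fixtures() -> list[str]:
    root = resources.files("cfscreen") / "fixtures"
    return sorted(f.name for f in root.iterdir() if f.name.endswith(".tsv"))


# -- calls and truth --------------------------------------------------------

def write_bed(calls: list[CnvCall], path) -> None:
    """CNV calls as sorted BED (0-based half-open)."""
    rows = sorted(calls, key=lambda c: (c.chromosome, c.start_bp))
    with open(path, "w") as fh:
        for c in rows:
            name = f"{c.state};origin={c.origin};z={c.segment_z:.2f}"
            fh.write(f"{c.chromosome}\t{c.start_bp}\t{c.end_bp}\t{name}\n")


def write_truth(truth: SimTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1)


def read_truth(path) -> SimTruth:
    with open(path) as fh:
        return SimTruth.from_dict(json.load(fh))


# -- configuration ----------------------------------------------------------

def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    seg = raw.pop("segmentation", None)
    cfg = RunConfig(**raw)
    if seg:
        cfg.segmentation = SegmentationConfig(**seg)
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)


def config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(asdict(cfg), sort_keys=True).encode()
    ).hexdigest()[:12]


def log_run_context(cfg: RunConfig, seed: int, fixtures: list[str] | None = None) -> None:
    """Record config hash, seed and fixture checksums for reproducibility."""
    logger.info("config_hash=%s seed=%d", config_hash(cfg), seed)
    for name in fixtures or []:
        digest = hashlib.sha256(fixture_path(name).read_bytes()).hexdigest()[:12]
        logger.info("fixture %s sha256=%s", name, digest)
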