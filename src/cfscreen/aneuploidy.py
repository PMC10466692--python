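"""Per-chromosome Z-score aneuploidy calling against a euploid panel.

Each sample's GC-corrected read mass is reduced to per-chromosome
fractions; a reference panel of euploid pregnancies supplies the mean and
SD of each fraction, and the standardized deviation

    z_c = (x_c − μ_c) / σ_c

is thresholded at |z| ≥ 3 (the positivity rule).  Because the panel is
finite, the plain statistic is sqrt(1+1/n)·t_{n−1} distributed under the
null rather than standard normal; :meth:`ReferencePanel.calibrate_z` maps
it to the normal scale so the threshold keeps its nominal 0.27% two-sided
false-positive rate regardless of panel size.

Sex-chromosome karyotypes (45,X / 47,XXX / 47,XXY / 47,XYY) come from a
decision table over the X z-score, chrY presence and the chrY mass excess
expected for a single Y at the measured fetal fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genome import AUTOSOMES
from .windows import BinTable

__all__ = [
    "ReferencePanel",
    "AneuploidyCall",
    "chromosome_fractions",
    "build_panel",
    "z_score",
    "call_autosomes",
    "call_sex_chromosomes",
]

Z_THRESHOLD = 3.0


def chromosome_fractions(bins: BinTable) -> dict[str, float]:
    """Per-chromosome share of GC-corrected read mass (sums to 1)."""
    values = bins.corrected_ratio
    if values is None:
        raise ValueError("bins must be GC-corrected first")
    if values.size == 0:
        raise ValueError("empty bin table")
    chrom = np.asarray(bins.chrom, dtype=object)
    total = float(values.sum())
    # windows are grouped by chromosome; sum each contiguous block
    block_starts = np.concatenate(
        [[0], np.flatnonzero(chrom[1:] != chrom[:-1]) + 1]
    )
    labels = [str(c) for c in chrom[block_starts]]
    if len(set(labels)) != len(labels):
        raise ValueError("windows of one chromosome must be contiguous")
    sums = np.add.reduceat(values, block_starts)
    return {c: float(s / total) for c, s in zip(labels, sums)}


@dataclass
class ReferencePanel:
    """Euploid reference: mean/SD of chromosomal fractions.

    ``mean``/``sd`` hold all-chromosome fractions (sum of means is 1);
    ``auto_mean``/``auto_sd`` hold fractions renormalized over autosomes
    only, which makes the autosomal statistics independent of fetal sex.
    """

    chromosomes: tuple[str, ...]
    mean: dict[str, float]
    sd: dict[str, float]
    auto_mean: dict[str, float]
    auto_sd: dict[str, float]
    n: int
    seed: int | None = None

    def calibrate_z(self, z: float | np.ndarray) -> float | np.ndarray:
        """Map the finite-panel statistic to the standard-normal scale.

        Under the null, (x−μ̂)/σ̂ = sqrt(1+1/n)·t_{n−1}; the returned score
        is the normal quantile of the matching t probability, computed on
        whichever tail is smaller for numerical stability at large |z|.
        """
        t = np.asarray(z, float) / np.sqrt(1.0 + 1.0 / self.n)
        tail = stats.t.sf(np.abs(t), df=self.n - 1)
        out = np.sign(t) * -stats.norm.ppf(np.clip(tail, 1e-315, 1.0))
        return float(out) if np.isscalar(z) else out


def build_panel(
    euploid_samples: list[BinTable] | list[dict[str, float]],
    seed: int | None = None,
) -> ReferencePanel:
    """Estimate per-chromosome mean/SD from ≥ 20 euploid samples."""
    if len(euploid_samples) < 20:
        raise ValueError("need at least 20 euploid samples for a panel")
    rows = [
        s if isinstance(s, dict) else chromosome_fractions(s)
        for s in euploid_samples
    ]
    chroms = tuple(rows[0])
    mat = np.array([[r[c] for c in chroms] for r in rows], float)
    sd = mat.std(axis=0, ddof=1)
    degenerate = sd <= 1e-12 * np.maximum(mat.mean(axis=0), 1e-300)
    if np.any(degenerate):
        bad = [c for c, d in zip(chroms, degenerate) if d]
        raise ValueError(f"degenerate panel: zero SD on {', '.join(bad)}")
    autos = [c for c in chroms if c in AUTOSOMES]
    ai = [chroms.index(c) for c in autos]
    amat = mat[:, ai] / mat[:, ai].sum(axis=1, keepdims=True)
    asd = amat.std(axis=0, ddof=1)
    return ReferencePanel(
        chromosomes=chroms,
        mean={c: float(m) for c, m in zip(chroms, mat.mean(axis=0))},
        sd={c: float(s) for c, s in zip(chroms, sd)},
        auto_mean={c: float(m) for c, m in zip(autos, amat.mean(axis=0))},
        auto_sd={c: float(s) for c, s in zip(autos, asd)},
        n=len(rows),
        seed=seed,
    )


def z_score(
    sample_fractions: dict[str, float], panel: ReferencePanel
) -> dict[str, float]:
    """Plain panel z-scores, z_c = (x_c − μ_c)/σ_c."""
    missing = [c for c in sample_fractions if c not in panel.mean]
    if missing:
        raise ValueError(f"panel does not cover {', '.join(missing)}")
    return {
        c: (x - panel.mean[c]) / panel.sd[c] for c, x in sample_fractions.items()
    }


@dataclass
class AneuploidyCall:
    chromosome: str
    z: float
    call: str  # trisomy | monosomy | none
    sca_karyotype: str | None = None
    ff_used: float | None = None


def call_autosomes(
    z: dict[str, float], threshold: float = Z_THRESHOLD
) -> list[AneuploidyCall]:
    """Threshold autosomal z-scores into trisomy/monosomy calls.

    Common trisomies (21/18/13) and rare autosomal trisomies are called by
    the same rule on their own chromosomes.
    """
    calls = []
    for c in AUTOSOMES:
        if c not in z:
            continue
        zc = z[c]
        if zc >= threshold:
            calls.append(AneuploidyCall(chromosome=c, z=zc, call="trisomy"))
        elif zc <= -threshold:
            calls.append(AneuploidyCall(chromosome=c, z=zc, call="monosomy"))
    return calls


def call_sex_chromosomes(
    zx: float,
    zy: float | None,
    y_fraction: float,
    ff: float,
    background_y: float,
    male_reference_y: float,
    y_sd: float,
    threshold: float = Z_THRESHOLD,
    y_presence_sds: float = 4.0,
    xyy_factor: float = 1.5,
) -> str | None:
    """Sex-chromosome karyotype decision table.

    Y presence means a chrY mass fraction more than ``y_presence_sds``
    female-panel SDs above background.  The 47,XYY arm compares the chrY
    excess with ``xyy_factor`` times the single-Y expectation at the
    measured fetal fraction (a 47,XYY placenta sheds twice that excess).

    ``zx`` must already be referenced to the expected X mass for the
    fetal sex (the pipeline rescales the female-panel mean by 1 − ff/2
    when Y is present).
    """
    if ff is None:
        return None
    y_excess = y_fraction - background_y
    y_present = y_excess > y_presence_sds * y_sd
    single_y = ff * (male_reference_y - background_y)
    if not y_present:
        if zx <= -threshold:
            return "45,X"
        if zx >= threshold:
            return "47,XXX"
        return None
    if zx >= threshold:
        return "47,XXY"
    if y_excess >= xyy_factor * single_y:
        return "47,XYY"
    return None
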