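"""Chromatographic fingerprinting and similarity analysis.

Builds the consensus fingerprint of a batch set: common peaks matched
across batches by retention time, a reference peak, relative retention
times (RRT) and relative peak areas (RPA) against it, the simulative
mean chromatogram (mean fusion vector), per-batch similarity indexes
(Pearson correlation by default, cosine as an option), and the
characteristic-peak subset whose prevalence across batches meets the
fingerprint threshold.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .signal import Chromatogram, PeakTable


@dataclass
class CommonPeakTable:
    """Common peaks of a batch set and their per-batch measurements.

    ``areas`` and ``rts`` are (n_batches, n_common_peaks) matrices; a
    batch lacking a peak holds area 0 and RT NaN.  ``rrts``/``rpas`` are
    filled by :func:`relative_metrics`.
    """

    batch_ids: list[str]
    mean_rts: np.ndarray
    prevalence: np.ndarray
    areas: np.ndarray
    rts: np.ndarray
    rrts: np.ndarray | None = None
    rpas: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.mean_rts) <= 0):
            raise ValueError("common-peak mean RTs must be strictly increasing")
        if np.any(self.prevalence <= 0) or np.any(self.prevalence > 1):
            raise ValueError("prevalence must lie in (0, 1]")

    @property
    def n_peaks(self) -> int:
        return len(self.mean_rts)

    @property
    def n_batches(self) -> int:
        return len(self.batch_ids)


def match_common_peaks(tables: list[PeakTable], rt_tolerance: float = 0.10) -> CommonPeakTable:
    """Match peaks across batches into common peaks by retention time.

    Single-linkage agglomeration along the RT axis: the closest pair of
    clusters merges while their gap is within ``rt_tolerance`` and the
    merged cluster's RT spread stays within twice the tolerance; ties go
    to the earlier-eluting pair.  One cluster is one common peak.  When a
    batch contributes several peaks to a cluster the largest-area one is
    kept.
    """
    if not tables:
        raise ValueError("need at least one peak table")
    if len(tables) < 2:
        raise ValueError("need at least two batches to define common peaks")

    entries = []  # (rt, batch_index, area)
    for b, table in enumerate(tables):
        for p in table:
            entries.append((p.apex_rt, b, p.area))
    entries.sort(key=lambda e: e[0])
    clusters: list[list[tuple[float, int, float]]] = [[e] for e in entries]

    def span(c):  # RT diameter of a cluster
        return c[-1][0] - c[0][0]

    while len(clusters) > 1:
        gaps = [
            (clusters[i + 1][0][0] - clusters[i][-1][0], i) for i in range(len(clusters) - 1)
        ]
        gap, i = min(gaps)  # ties resolve to the earlier-eluting pair
        if gap > rt_tolerance:
            break
        merged = clusters[i] + clusters[i + 1]
        if merged[-1][0] - merged[0][0] > 2 * rt_tolerance:
            # The closest admissible pair may not be the global minimum.
            admissible = [
                (g, j)
                for g, j in gaps
                if g <= rt_tolerance
                and clusters[j + 1][-1][0] - clusters[j][0][0] <= 2 * rt_tolerance
            ]
            if not admissible:
                break
            gap, i = min(admissible)
            merged = clusters[i] + clusters[i + 1]
        clusters[i : i + 2] = [merged]

    n_b, n_p = len(tables), len(clusters)
    areas = np.zeros((n_b, n_p))
    rts = np.full((n_b, n_p), np.nan)
    mean_rts = np.empty(n_p)
    prevalence = np.empty(n_p)
    for j, cluster in enumerate(clusters):
        mean_rts[j] = float(np.mean([rt for rt, _, _ in cluster]))
        present = set()
        for rt, b, area in cluster:
            present.add(b)
            if area > areas[b, j]:
                areas[b, j] = area
                rts[b, j] = rt
        prevalence[j] = len(present) / n_b
    return CommonPeakTable(
        batch_ids=[t.batch_id for t in tables],
        mean_rts=mean_rts,
        prevalence=prevalence,
        areas=areas,
        rts=rts,
    )


def select_reference_peak(cpt: CommonPeakTable, strategy: str = "max-mean-area-ubiquitous") -> int:
    """Choose the reference peak for relative metrics.

    ``"max-mean-area-ubiquitous"`` (default): among peaks present in
    every batch, the one with the highest mean area.  ``"fixed-rt:<t>"``:
    the common peak whose mean RT is nearest ``t`` minutes.
    """
    ubiquitous = np.flatnonzero(cpt.prevalence >= 1.0)
    if strategy == "max-mean-area-ubiquitous":
        if ubiquitous.size == 0:
            raise ValueError("no common peak is present in every batch")
        means = cpt.areas[:, ubiquitous].mean(axis=0)
        return int(ubiquitous[int(np.argmax(means))])
    if strategy.startswith("fixed-rt:"):
        target = float(strategy.split(":", 1)[1])
        return int(np.argmin(np.abs(cpt.mean_rts - target)))
    raise ValueError(f"unknown reference-peak strategy {strategy!r}")


def relative_metrics(cpt: CommonPeakTable, ref_index: int) -> CommonPeakTable:
    """Fill RRT and RPA matrices against the reference peak.

    rrt[b, p] = rt[b, p] / rt[b, ref]; rpa[b, p] = area[b, p] /
    area[b, ref].  Every batch must actually contain the reference peak.
    """
    if not 0 <= ref_index < cpt.n_peaks:
        raise ValueError(f"reference index {ref_index} out of range")
    ref_areas = cpt.areas[:, ref_index]
    zero = np.flatnonzero(ref_areas <= 0)
    if zero.size:
        raise ValueError(
            f"reference peak area is zero in batch {cpt.batch_ids[int(zero[0])]}"
        )
    rrts = cpt.rts / cpt.rts[:, [ref_index]]
    rpas = cpt.areas / ref_areas[:, None]
    return dataclasses.replace(cpt, rrts=rrts, rpas=rpas)


def mean_fusion(chroms: list[Chromatogram]) -> np.ndarray:
    """Simulative mean chromatogram: the pointwise mean of the traces.

    All traces must share one time grid (resample first if not).
    """
    if not chroms:
        raise ValueError("need at least one chromatogram")
    grid = chroms[0].time
    for c in chroms[1:]:
        if c.time.shape != grid.shape or not np.allclose(c.time, grid, atol=1e-9):
            raise ValueError("chromatograms are on different grids; resample first")
    return np.mean([c.intensity for c in chroms], axis=0)


def similarity(chrom: Chromatogram, mean_vector: np.ndarray, mode: str = "correlation") -> float:
    """Similarity index of a trace against the simulative mean chromatogram.

    ``"correlation"`` (default) is the Pearson correlation coefficient;
    ``"cosine"`` the cosine of the angle between the raw vectors.  A
    zero-variance (or zero-norm) input is undefined and returns NaN.
    """
    x = np.asarray(chrom.intensity, dtype=float)
    y = np.asarray(mean_vector, dtype=float)
    if x.shape != y.shape:
        raise ValueError("trace and mean vector lengths differ")
    if mode == "correlation":
        xc = x - x.mean()
        yc = y - y.mean()
        denom = np.sqrt((xc @ xc) * (yc @ yc))
        if denom == 0:
            return float("nan")
        return float((xc @ yc) / denom)
    if mode == "cosine":
        denom = np.sqrt((x @ x) * (y @ y))
        if denom == 0:
            return float("nan")
        return float((x @ y) / denom)
    raise ValueError(f"unknown similarity mode {mode!r}")


def similarity_report(
    chroms: list[Chromatogram], mean_vector: np.ndarray, mode: str = "correlation"
) -> pd.DataFrame:
    """Per-batch similarity table (columns batch_id, similarity, mode)."""
    return pd.DataFrame(
        {
            "batch_id": [c.batch_id for c in chroms],
            "similarity": [similarity(c, mean_vector, mode) for c in chroms],
            "mode": mode,
        }
    )


def peak_vector_similarity(cpt: CommonPeakTable, batch_index: int, mode: str = "correlation") -> float:
    """Similarity of one batch's common-peak area vector to the mean vector.

    Alternative to full-trace similarity for workflows that compare the
    few-dimensional peak-area fingerprints instead of raw traces.
    """
    x = cpt.areas[batch_index]
    m = cpt.areas.mean(axis=0)
    if mode == "correlation":
        xc, mc = x - x.mean(), m - m.mean()
        denom = np.sqrt((xc @ xc) * (mc @ mc))
        return float("nan") if denom == 0 else float((xc @ mc) / denom)
    if mode == "cosine":
        denom = np.sqrt((x @ x) * (m @ m))
        return float("nan") if denom == 0 else float((x @ m) / denom)
    raise ValueError(f"unknown similarity mode {mode!r}")


def characteristic_peaks(cpt: CommonPeakTable, prevalence_threshold: float = 0.9) -> list[int]:
    """Indices of common peaks with prevalence >= the threshold."""
    if not 0 < prevalence_threshold <= 1:
        raise ValueError("prevalence_threshold must lie in (0, 1]")
    return [int(j) for j in np.flatnonzero(cpt.prevalence >= prevalence_threshold)]


@dataclass
class FingerprintModel:
    """A material's consensus fingerprint.

    Holds the reference-peak index into the common-peak table, the mean
    fusion vector on the shared time grid, the characteristic-peak
    indices and the species label the model represents.
    """

    reference_peak_index: int
    time: np.ndarray
    mean_vector: np.ndarray
    characteristic_peaks: list[int]
    common_peak_rts: np.ndarray
    species_label: str = ""

    def __post_init__(self) -> None:
        if len(self.time) != len(self.mean_vector):
            raise ValueError("mean_vector length must match the time grid")
        if any(j < 0 or j >= len(self.common_peak_rts) for j in self.characteristic_peaks):
            raise ValueError("characteristic peaks must index common peaks")

    def save(self, path: str | Path) -> None:
        """Serialize as JSON with the mean vector in a sibling CSV."""
        path = Path(path)
        vec_path = path.with_suffix(".mean_vector.csv")
        pd.DataFrame({"time_min": self.time, "intensity_mau": self.mean_vector}).to_csv(
            vec_path, index=False
        )
        payload = {
            "reference_peak_index": self.reference_peak_index,
            "characteristic_peaks": list(self.characteristic_peaks),
            "common_peak_rts": [float(r) for r in self.common_peak_rts],
            "species_label": self.species_label,
            "mean_vector_csv": vec_path.name,
        }
        path.write_text(json.dumps(payload, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "FingerprintModel":
        path = Path(path)
        payload = json.loads(path.read_text())
        vec = pd.read_csv(path.parent / payload["mean_vector_csv"])
        return cls(
            reference_peak_index=payload["reference_peak_index"],
            time=vec["time_min"].to_numpy(),
            mean_vector=vec["intensity_mau"].to_numpy(),
            characteristic_peaks=list(payload["characteristic_peaks"]),
            common_peak_rts=np.asarray(payload["common_peak_rts"], dtype=float),
            species_label=payload.get("species_label", ""),
        )


def build_fingerprint(
    chroms: list[Chromatogram],
    tables: list[PeakTable],
    rt_tolerance: float = 0.10,
    prevalence_threshold: float = 0.9,
    reference_strategy: str = "max-mean-area-ubiquitous",
    species_label: str = "",
) -> tuple[FingerprintModel, CommonPeakTable]:
    """Assemble the fingerprint model of a batch set.

    ``chroms`` must be baseline-corrected and share a grid; ``tables``
    are their detected peak tables in the same order.
    """
    if len(chroms) != len(tables):
        raise ValueError("one peak table per chromatogram required")
    cpt = match_common_peaks(tables, rt_tolerance=rt_tolerance)
    ref = select_reference_peak(cpt, strategy=reference_strategy)
    cpt = relative_metrics(cpt, ref)
    vec = mean_fusion(chroms)
    model = FingerprintModel(
        reference_peak_index=ref,
        time=chroms[0].time,
        mean_vector=vec,
        characteristic_peaks=characteristic_peaks(cpt, prevalence_threshold),
        common_peak_rts=cpt.mean_rts,
        species_label=species_label,
    )
    return model, cpt
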