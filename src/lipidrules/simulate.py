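"""Ground-truthed synthetic DDA data generation.

The simulator plants library entries as chromatographic peaks (Gaussian in
retention time) and emits the three inputs the annotation pipeline
consumes: a feature table, an .ms2 file of data-dependent scans, and a
ground-truth manifest stating which identifications at which confidence and
rank the data supports.

Co-eluting isobaric lipids planted at the same precursor m/z share a
feature; their fragment peaks coexist in each scan, and peaks closer than a
small m/z merge window are summed — so shared fragments inflate both
candidates' summed intensities, reproducing the known ranking pathology of
intensity-sum ranking.  Scans offset from a lipid's apex sample it below
its apex intensity.  Noise peaks are uniform in m/z.

Everything is reproducible: one seed fixes all randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import Feature, MS2Spectrum, write_ms2
from .engine import IdentificationRule
from .library import LibraryEntry

__all__ = [
    "PlantedLipid",
    "SimulationConfig",
    "SimulatedDataset",
    "simulate",
    "write_simulation",
    "two_isomer_scenario",
    "shared_fragment_scenario",
    "off_apex_scenario",
]


@dataclass(frozen=True)
class PlantedLipid:
    """One lipid planted into the simulated run.

    Fragment peak intensity at RT t is
    ``precursor_intensity * scale * exp(-(t-apex)^2 / (2 width^2))`` with
    ``scale`` from ``fragment_scales`` (default ``default_fragment_scale``).
    A scale of 0 suppresses that fragment entirely.
    """

    entry: LibraryEntry
    apex_rt: float
    precursor_intensity: float
    peak_width_min: float = 0.08
    default_fragment_scale: float = 0.2
    fragment_scales: tuple[tuple[str, float], ...] = ()

    def __post_init__(self):
        if self.precursor_intensity <= 0 or self.peak_width_min <= 0:
            raise ValueError("intensities and peak width must be > 0")

    def scale_for(self, label: str) -> float:
        for lab, s in self.fragment_scales:
            if lab == label:
                return s
        return self.default_fragment_scale

    def fragment_intensity(self, label: str, rt: float) -> float:
        g = np.exp(-((rt - self.apex_rt) ** 2) / (2 * self.peak_width_min**2))
        return float(self.precursor_intensity * self.scale_for(label) * g)


@dataclass(frozen=True)
class SimulationConfig:
    planted: tuple[PlantedLipid, ...]
    n_scans: int = 5
    scan_rt_offsets: tuple[float, ...] | None = None  # minutes, around apex
    noise_peaks_per_scan: int = 0
    noise_intensity_range: tuple[float, float] = (50.0, 500.0)
    noise_mz_range: tuple[float, float] = (100.0, 1100.0)
    mz_jitter_ppm: float = 0.0
    seed: int = 0
    feature_cluster_mz_tol: float = 0.005
    feature_cluster_rt_tol: float = 0.2
    peak_merge_ppm: float = 3.0
    manifest_min_intensity: float = 1000.0

    def __post_init__(self):
        if not self.planted:
            raise ValueError("at least one planted lipid required")
        if self.mz_jitter_ppm < 0:
            raise ValueError("mz jitter must be >= 0")
        pols = {p.entry.adduct.polarity for p in self.planted}
        if len(pols) > 1:
            raise ValueError("all planted lipids must share one polarity")

    @property
    def polarity(self) -> str:
        return self.planted[0].entry.adduct.polarity

    def offsets(self) -> tuple[float, ...]:
        if self.scan_rt_offsets is not None:
            return self.scan_rt_offsets
        width = max(p.peak_width_min for p in self.planted)
        if self.n_scans == 1:
            return (0.0,)
        return tuple(np.linspace(-width, width, self.n_scans))


@dataclass
class SimulatedDataset:
    features: list[Feature]
    spectra: list[MS2Spectrum]
    manifest: pd.DataFrame  # ground truth, one row per planted identification


def _cluster_features(
    config: SimulationConfig,
) -> list[list[PlantedLipid]]:
    clusters: list[list[PlantedLipid]] = []
    for p in sorted(
        config.planted, key=lambda x: (x.entry.precursor_mz, x.apex_rt)
    ):
        placed = False
        for cl in clusters:
            ref = cl[0]
            if (
                abs(p.entry.precursor_mz - ref.entry.precursor_mz)
                <= config.feature_cluster_mz_tol
                and abs(p.apex_rt - ref.apex_rt) <= config.feature_cluster_rt_tol
            ):
                cl.append(p)
                placed = True
                break
        if not placed:
            clusters.append([p])
    return clusters


def _expected_confidence(
    planted: PlantedLipid,
    rule: IdentificationRule | None,
    min_intensity: float,
) -> int:
    """Confidence the planted peak intensities support at the apex,
    evaluated directly on the planted ground truth (no scan matching)."""
    if rule is None:
        return 4
    supported = {
        label
        for label, _ in planted.entry.fragments
        if planted.fragment_intensity(label, planted.apex_rt) >= min_intensity
    }
    if all(g.satisfied(supported) for g in rule.groups):
        return 1
    class_groups = [g for g in rule.groups if g.kind == "class"]
    if class_groups and all(g.satisfied(supported) for g in class_groups):
        return 3
    return 4


def simulate(
    config: SimulationConfig,
    rules: list[IdentificationRule] | None = None,
) -> SimulatedDataset:
    """Generate features, DDA scans and the ground-truth manifest."""
    rng = np.random.default_rng(config.seed)
    rule_map = {}
    if rules is not None:
        rule_map = {(r.class_name, r.adduct_name): r for r in rules}

    clusters = _cluster_features(config)
    features: list[Feature] = []
    spectra: list[MS2Spectrum] = []
    manifest_rows: list[dict] = []
    scan_number = 0
    offsets = config.offsets()

    for ci, cluster in enumerate(clusters, start=1):
        total = sum(p.precursor_intensity for p in cluster)
        mz = sum(
            p.entry.precursor_mz * p.precursor_intensity for p in cluster
        ) / total
        apex = sum(p.apex_rt * p.precursor_intensity for p in cluster) / total
        if config.mz_jitter_ppm:
            mz += mz * 1e-6 * rng.normal(0.0, config.mz_jitter_ppm)
        fid = f"SIM{ci}"
        features.append(Feature(fid, mz, apex))

        for off in offsets:
            scan_number += 1
            rt = apex + off
            raw: list[tuple[float, float]] = []
            for p in cluster:
                for label, fmz in p.entry.fragments:
                    inten = p.fragment_intensity(label, rt)
                    if inten <= 0:
                        continue
                    if config.mz_jitter_ppm:
                        fmz = fmz + fmz * 1e-6 * rng.normal(
                            0.0, config.mz_jitter_ppm
                        )
                    raw.append((fmz, inten))
            for _ in range(config.noise_peaks_per_scan):
                nmz = rng.uniform(*config.noise_mz_range)
                nint = rng.uniform(*config.noise_intensity_range)
                raw.append((float(nmz), float(nint)))
            # co-added ion current: peaks within the merge window sum
            raw.sort(key=lambda x: x[0])
            merged: list[tuple[float, float]] = []
            for pmz, pint in raw:
                if (
                    merged
                    and (pmz - merged[-1][0]) <= merged[-1][0] * 1e-6 * config.peak_merge_ppm
                ):
                    omz, oint = merged[-1]
                    tot = oint + pint
                    merged[-1] = ((omz * oint + pmz * pint) / tot, tot)
                else:
                    merged.append((pmz, pint))
            spectra.append(
                MS2Spectrum(scan_number, mz, rt, tuple(merged))
            )

        # ground truth: planted abundance order within the feature
        ranked = sorted(
            cluster,
            key=lambda p: (
                -sum(
                    p.fragment_intensity(label, p.apex_rt)
                    for label, _ in p.entry.fragments
                ),
                p.entry.annotation_text,
            ),
        )
        for rank, p in enumerate(ranked, start=1):
            rule = rule_map.get((p.entry.class_name, p.entry.adduct.name))
            manifest_rows.append(
                {
                    "feature_id": fid,
                    "feature_mz": round(mz, 6),
                    "feature_rt": round(apex, 4),
                    "class": p.entry.class_name,
                    "annotation": p.entry.annotation_text,
                    "adduct": p.entry.adduct.name,
                    "expected_confidence": _expected_confidence(
                        p, rule, config.manifest_min_intensity
                    )
                    if rules is not None
                    else "",
                    "planted_intensity": round(p.precursor_intensity, 2),
                    "planted_fragment_sum": round(
                        sum(
                            p.fragment_intensity(label, p.apex_rt)
                            for label, _ in p.entry.fragments
                        ),
                        2,
                    ),
                    "expected_rank": rank,
                }
            )
    return SimulatedDataset(
        features=features,
        spectra=spectra,
        manifest=pd.DataFrame(manifest_rows),
    )


def write_simulation(
    dataset: SimulatedDataset,
    out_dir: str | Path,
    polarity: str,
    stem: str = "sim",
) -> dict[str, Path]:
    """Write the dataset as the file set the pipeline discovers: a feature
    table (``<stem>_pos.csv``/``_neg.csv``), a DDA .ms2 file and the
    manifest.  Same seed, same bytes."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    suffix = "pos" if polarity == "positive" else "neg"
    table_path = out_dir / f"{stem}_{suffix}.csv"
    ms2_path = out_dir / f"{stem}_dd_{suffix}.ms2"
    manifest_path = out_dir / f"{stem}_manifest.csv"
    pd.DataFrame(
        {
            "row ID": [f.feature_id for f in dataset.features],
            "row m/z": [f"{f.mz:.6f}" for f in dataset.features],
            "row retention time": [f"{f.rt:.4f}" for f in dataset.features],
        }
    ).to_csv(table_path, index=False)
    write_ms2(dataset.spectra, ms2_path)
    dataset.manifest.to_csv(manifest_path, index=False)
    return {"features": table_path, "ms2": ms2_path, "manifest": manifest_path}


# ---------------------------------------------------------------------------
# Canonical test scenarios

def _entry(class_name: str, chains, adduct: str) -> LibraryEntry:
    from .chem import FattyAcyl
    from .library import build_library, default_classes

    cdef = default_classes()[class_name]
    chain_objs = tuple(
        c if isinstance(c, FattyAcyl) else FattyAcyl(*c) for c in chains
    )
    return build_library(cdef, [chain_objs], [adduct])[0]


def two_isomer_scenario(seed: int = 0) -> SimulationConfig:
    """Two co-eluting PC(38:6) formate-adduct isomers on one feature at
    m/z 850.5604 / RT 5.92, distinguishable only by their fatty-acyl
    carboxylate fragments; the first is planted more abundant."""
    a = _entry("PC", [(16, 0), (22, 6)], "[M+HCO2]-")
    b = _entry("PC", [(18, 2), (20, 4)], "[M+HCO2]-")
    return SimulationConfig(
        planted=(
            PlantedLipid(a, apex_rt=5.92, precursor_intensity=2.0e5),
            PlantedLipid(b, apex_rt=5.92, precursor_intensity=8.0e4),
        ),
        n_scans=4,
        seed=seed,
    )


def shared_fragment_scenario(seed: int = 0) -> SimulationConfig:
    """Three co-eluting TG(52:2) ammonium-adduct isomers where the rare
    isomer shares its 16:0 neutral-loss fragment with the abundant one.
    Peak co-addition inflates the rare isomer's summed fragment intensity,
    so the engine's ranking deviates from planted abundance order —
    expected behaviour of intensity-sum ranking, not a defect."""
    abundant = _entry("TG", [(16, 0), (18, 1), (18, 1)], "[M+NH4]+")
    rare_sharing = _entry("TG", [(16, 0), (18, 0), (18, 2)], "[M+NH4]+")
    # same sum composition (52:2) but no chain in common with the others
    middle = _entry("TG", [(15, 0), (17, 1), (20, 1)], "[M+NH4]+")
    return SimulationConfig(
        planted=(
            PlantedLipid(abundant, apex_rt=14.5, precursor_intensity=5.0e5),
            PlantedLipid(middle, apex_rt=14.5, precursor_intensity=1.0e5),
            PlantedLipid(rare_sharing, apex_rt=14.5, precursor_intensity=4.0e4),
        ),
        n_scans=4,
        seed=seed,
    )


def off_apex_scenario(seed: int = 0) -> SimulationConfig:
    """Two equally abundant PC formate isomers whose apexes differ; scans
    are taken at the first lipid's apex, so the off-apex lipid's fragments
    are sampled down the side of its peak and its summed intensity drops."""
    on_apex = _entry("PC", [(16, 0), (22, 6)], "[M+HCO2]-")
    off_apex = _entry("PC", [(18, 2), (20, 4)], "[M+HCO2]-")
    return SimulationConfig(
        planted=(
            PlantedLipid(on_apex, apex_rt=5.92, precursor_intensity=1.0e5,
                         peak_width_min=0.05),
            PlantedLipid(off_apex, apex_rt=6.02, precursor_intensity=1.0e5,
                         peak_width_min=0.05),
        ),
        n_scans=3,
        # the merged feature RT is 5.97; these scans sit at the first
        # lipid's apex and down the flank of the second's
        scan_rt_offsets=(-0.05, -0.04, -0.03),
        feature_cluster_rt_tol=0.2,
        seed=seed,
    )
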