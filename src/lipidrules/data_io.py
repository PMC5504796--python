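"""Reading feature tables and MS2 spectra, input discovery by filename
conventions, and writing annotated outputs.

Feature tables are delimited text with one row per feature; the m/z and
retention-time columns are auto-detected from common header names (MZmine's
"row m/z"/"row retention time" dialect included) and every other column is
preserved verbatim — annotation is strictly additive.

Retention times are minutes everywhere.  MS2 files use the open text
dialect produced by MSConvert: "H" header lines, "S <scan> <scan>
<precursor m/z>" blocks, "I RTime <minutes>" metadata and "<m/z>
<intensity>" peak lines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "Feature",
    "FeatureTable",
    "MS2Spectrum",
    "Job",
    "JobPlan",
    "read_feature_table",
    "read_ms2",
    "write_ms2",
    "discover_inputs",
    "write_outputs",
]

_MZ_COLUMN_NAMES = ("row m/z", "m/z", "mz", "precursor m/z", "mass")
_RT_COLUMN_NAMES = (
    "row retention time",
    "retention time",
    "rt",
    "row rt",
    "retention time (min)",
)
_ID_COLUMN_NAMES = ("row id", "id", "feature id", "feature_id")


@dataclass(frozen=True)
class Feature:
    feature_id: str
    mz: float
    rt: float  # minutes

    def __post_init__(self):
        if self.mz <= 0:
            raise ValueError(f"feature {self.feature_id}: m/z must be > 0")
        if self.rt < 0:
            raise ValueError(f"feature {self.feature_id}: RT must be >= 0")


@dataclass
class FeatureTable:
    """A parsed feature table: the original DataFrame (all columns
    preserved, order untouched) plus the detected column roles."""

    df: pd.DataFrame
    mz_column: str
    rt_column: str
    id_column: str | None = None
    path: Path | None = None

    @property
    def features(self) -> list[Feature]:
        ids = (
            self.df[self.id_column].astype(str)
            if self.id_column
            else pd.Series(
                [f"F{i + 1}" for i in range(len(self.df))], index=self.df.index
            )
        )
        return [
            Feature(str(fid), float(mz), float(rt))
            for fid, mz, rt in zip(
                ids, self.df[self.mz_column], self.df[self.rt_column]
            )
        ]


def _detect_column(columns, candidates, override, kind, path):
    if override is not None:
        if override not in columns:
            raise ValueError(
                f"{path}: requested {kind} column {override!r} not in header "
                f"{list(columns)}"
            )
        return override
    lowered = {str(c).strip().lower(): c for c in columns}
    for cand in candidates:
        if cand in lowered:
            return lowered[cand]
    raise ValueError(
        f"{path}: no {kind} column detected (looked for {list(candidates)}; "
        f"headers seen: {list(columns)})"
    )


def read_feature_table(
    path: str | Path,
    mz_column: str | None = None,
    rt_column: str | None = None,
) -> FeatureTable:
    """Read a delimited feature table, auto-detecting m/z and RT columns by
    case-insensitive header match unless overridden."""
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    mz_col = _detect_column(df.columns, _MZ_COLUMN_NAMES, mz_column, "m/z", path)
    rt_col = _detect_column(df.columns, _RT_COLUMN_NAMES, rt_column, "RT", path)
    lowered = {str(c).strip().lower(): c for c in df.columns}
    id_col = next(
        (lowered[c] for c in _ID_COLUMN_NAMES if c in lowered), None
    )
    if id_col is not None and df[id_col].astype(str).duplicated().any():
        id_col = None  # fall back to positional ids rather than reject
    feats = FeatureTable(df, mz_col, rt_col, id_col, path)
    ids = [f.feature_id for f in feats.features]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate feature ids")
    return feats


# ---------------------------------------------------------------------------
# MS2 text format

@dataclass(frozen=True)
class MS2Spectrum:
    scan_number: int
    precursor_mz: float
    rt: float  # minutes
    peaks: tuple[tuple[float, float], ...]  # (m/z, intensity), m/z ascending

    def __post_init__(self):
        if self.precursor_mz <= 0:
            raise ValueError(f"scan {self.scan_number}: precursor m/z must be > 0")
        object.__setattr__(
            self, "peaks", tuple(sorted(self.peaks, key=lambda p: p[0]))
        )


def read_ms2(path: str | Path, rt_in_seconds: bool = False) -> list[MS2Spectrum]:
    """Parse an .ms2 text file into spectra.

    One spectrum per "S" block; RT comes from the "I RTime" (or "I RetTime")
    line and is taken as minutes unless ``rt_in_seconds`` is set — no unit
    heuristics are applied.
    """
    path = Path(path)
    spectra: list[MS2Spectrum] = []
    scan: int | None = None
    precursor: float | None = None
    rt: float | None = None
    peaks: list[tuple[float, float]] = []
    last_s_line = 0

    def flush(lineno: int):
        nonlocal scan, precursor, rt, peaks
        if scan is None:
            return
        if rt is None:
            raise ValueError(
                f"{path}:{last_s_line}: scan {scan} has no 'I RTime' line"
            )
        rt_min = rt / 60.0 if rt_in_seconds else rt
        spectra.append(MS2Spectrum(scan, precursor, rt_min, tuple(peaks)))
        scan, precursor, rt, peaks = None, None, None, []

    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("H"):
                continue
            fields = line.split()
            if fields[0] == "S":
                flush(lineno)
                if len(fields) != 4:
                    raise ValueError(
                        f"{path}:{lineno}: malformed S line "
                        f"(expected 'S scan scan precursor'): {line!r}"
                    )
                try:
                    scan = int(fields[1])
                    precursor = float(fields[3])
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: malformed S line: {line!r}")
                last_s_line = lineno
            elif fields[0] == "I":
                if len(fields) >= 3 and fields[1] in ("RTime", "RetTime"):
                    try:
                        rt = float(fields[2])
                    except ValueError:
                        raise ValueError(
                            f"{path}:{lineno}: malformed RT value: {line!r}"
                        )
            elif fields[0] == "Z":
                continue
            else:
                if scan is None:
                    raise ValueError(
                        f"{path}:{lineno}: peak line before any S line"
                    )
                if len(fields) != 2:
                    raise ValueError(
                        f"{path}:{lineno}: peak line must have exactly "
                        f"2 fields: {line!r}"
                    )
                try:
                    mz, intensity = float(fields[0]), float(fields[1])
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: malformed peak: {line!r}")
                if intensity < 0:
                    raise ValueError(
                        f"{path}:{lineno}: negative intensity: {line!r}"
                    )
                peaks.append((mz, intensity))
    flush(-1)
    return spectra


def write_ms2(spectra: list[MS2Spectrum], path: str | Path) -> None:
    """Write spectra in the .ms2 text dialect read by :func:`read_ms2`
    (6-decimal m/z, 2-decimal intensity)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("H\tCreationTool\tlipidrules\n")
        for s in spectra:
            fh.write(f"S\t{s.scan_number}\t{s.scan_number}\t{s.precursor_mz:.6f}\n")
            fh.write(f"I\tRTime\t{s.rt:.4f}\n")
            for mz, inten in s.peaks:
                fh.write(f"{mz:.6f} {inten:.2f}\n")


# ---------------------------------------------------------------------------
# Directory discovery

@dataclass
class Job:
    folder: Path
    feature_table: Path
    polarity: str  # "positive" | "negative"
    ms2_files: list[Path] = field(default_factory=list)
    mode: str = "dd"
    warnings: list[str] = field(default_factory=list)


@dataclass
class JobPlan:
    root: Path
    jobs: list[Job] = field(default_factory=list)
    unrecognized: list[Path] = field(default_factory=list)


def _polarity_from_stem(stem: str) -> str | None:
    """Polarity from a filename stem: "neg"/"pos" suffixes, or a single
    trailing "n"/"p" that is not part of a longer word (must follow a
    non-letter, so "…ion" never reads as negative)."""
    s = stem.lower()
    if s.endswith("neg"):
        return "negative"
    if s.endswith("pos"):
        return "positive"
    if s.endswith("n") and (len(s) == 1 or not s[-2].isalpha()):
        return "negative"
    if s.endswith("p") and (len(s) == 1 or not s[-2].isalpha()):
        return "positive"
    return None


def discover_inputs(root_dir: str | Path) -> JobPlan:
    """Build a job plan from a directory tree: the root plus one level of
    substrate subfolders.  Feature tables are .csv files with a polarity
    suffix; MS2 files are .ms2 files in the same folder with a matching
    polarity suffix; acquisition mode is "dd" or "aif" from the filename
    (case-insensitive; AIF files are reported but not assigned since only
    data-dependent analysis is implemented).  Non-conforming files are
    recorded, never silently dropped."""
    root = Path(root_dir)
    if not root.is_dir():
        raise FileNotFoundError(f"input directory not found: {root}")
    plan = JobPlan(root=root)
    folders = [root] + sorted(p for p in root.iterdir() if p.is_dir())
    for folder in folders:
        tables: list[tuple[Path, str]] = []
        ms2s: list[tuple[Path, str, str]] = []
        for f in sorted(folder.iterdir()):
            if not f.is_file():
                continue
            suffix = f.suffix.lower()
            if suffix == ".csv":
                pol = _polarity_from_stem(f.stem)
                if pol is None:
                    plan.unrecognized.append(f)
                else:
                    tables.append((f, pol))
            elif suffix == ".ms2":
                pol = _polarity_from_stem(f.stem)
                name = f.stem.lower()
                mode = "aif" if "aif" in name else ("dd" if "dd" in name else "dd")
                if pol is None:
                    plan.unrecognized.append(f)
                else:
                    ms2s.append((f, pol, mode))
            else:
                plan.unrecognized.append(f)
        for table, pol in tables:
            job = Job(folder=folder, feature_table=table, polarity=pol)
            for f, mpol, mode in ms2s:
                if mpol != pol:
                    continue
                if mode == "aif":
                    job.warnings.append(
                        f"{f.name}: AIF acquisition not supported, file skipped"
                    )
                    continue
                job.ms2_files.append(f)
            if not job.ms2_files:
                job.warnings.append(
                    "no MS2 file of matching polarity: identification degrades "
                    "to precursor-only (confidence 4)"
                )
            plan.jobs.append(job)
    return plan


# ---------------------------------------------------------------------------
# Outputs

_APPENDED_COLUMNS = (
    "top_annotation",
    "top_class",
    "top_adduct",
    "top_confidence",
    "top_summed_intensity",
    "all_ids",
)


def write_outputs(
    table: FeatureTable,
    results: dict[str, list],
    out_dir: str | Path,
    stem: str | None = None,
) -> dict[str, Path]:
    """Write the annotated feature table and per-class fragment-detail
    tables.

    ``results`` maps feature_id -> ranked list of Identification objects
    (see :mod:`lipidrules.engine`).  The annotated table is the input table
    with appended columns only; rows are never filtered or reordered.
    Returns a mapping of output kind to written path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = stem or (table.path.stem if table.path else "features")

    feats = table.features
    annotated = table.df.copy()
    cols = {c: [] for c in _APPENDED_COLUMNS}
    for feat in feats:
        ids = results.get(feat.feature_id, [])
        if ids:
            top = ids[0]
            cols["top_annotation"].append(top.annotation_text)
            cols["top_class"].append(top.class_name)
            cols["top_adduct"].append(top.adduct_name)
            cols["top_confidence"].append(top.confidence)
            cols["top_summed_intensity"].append(top.summed_intensity)
            cols["all_ids"].append(
                ";".join(
                    f"{i.confidence}|{i.annotation_text}|{i.adduct_name}|"
                    f"{i.summed_intensity:.1f}"
                    for i in ids
                )
            )
        else:
            for c in _APPENDED_COLUMNS:
                cols[c].append("")
    for c in _APPENDED_COLUMNS:
        annotated[c] = cols[c]
    annotated_path = out_dir / f"{stem}_annotated.csv"
    annotated.to_csv(annotated_path, index=False)
    written = {"annotated": annotated_path}

    # fragment-detail tables, one file per lipid class
    by_class: dict[str, list[dict]] = {}
    for feat in feats:
        for ident in results.get(feat.feature_id, []):
            for obs in ident.observations:
                by_class.setdefault(ident.class_name, []).append(
                    {
                        "feature_id": feat.feature_id,
                        "feature_mz": feat.mz,
                        "feature_rt": feat.rt,
                        "annotation": ident.annotation_text,
                        "adduct": ident.adduct_name,
                        "fragment": obs.label,
                        "theoretical_mz": round(obs.theoretical_mz, 6),
                        "n_scans": obs.n_scans,
                        "max_intensity": obs.max_intensity,
                        "mean_observed_mz": (
                            round(obs.mean_observed_mz, 6)
                            if obs.n_scans
                            else ""
                        ),
                        "rt_at_max": obs.rt_at_max if obs.n_scans else "",
                        "passes": int(obs.passes),
                    }
                )
    for class_name, rows in sorted(by_class.items()):
        p = out_dir / f"{stem}_{class_name}_fragments.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        written[class_name] = p
    return written
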