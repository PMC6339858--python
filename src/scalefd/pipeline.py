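"""End-to-end analysis: epoch preparation, fractal + spectral estimation,
group statistics, and a machine-readable run log.

The canonical preparation mirrors the emulated acquisition protocol: take the
leading 60 s of each recording, drop 5 s from each end (the segments touched
by the acquisition band-pass filter's edge effects), and estimate fractal
dimensions on the remaining 50 s (10,000 samples at 200 Hz).  The PSD is
computed on the untrimmed 60 s window — deliberately asymmetric with the
fractal path; see the methods note.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bands import BandScaleRange, band_to_scales, default_band_table
from .core import Epoch, scale_specific_dimension
from .errors import InputError, ScaleFDError
from .group_stats import (
    CohortTable,
    RmAnovaResult,
    TestResult,
    attach_fdr,
    covariate_correlation,
    log_transform,
    rm_anova,
    sensorwise_ttests,
)
from .io import Recording, read_recording
from .spectral import bin_psd, psd

__all__ = ["RunConfig", "RunResult", "prepare_epoch", "run_analysis", "load_cohort_dir"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one analysis run.

    ``bands=None`` means the canonical four-band table at the recording's
    sampling rate.  Band dicts may give ``{label, f_low, f_high}`` (mapped
    via the reciprocal rule) or additionally explicit ``k_min/k_max`` (the
    explicit window wins).
    """

    bands: tuple[BandScaleRange, ...] | None = None
    epoch_s: float = 60.0
    trim_s: float = 5.0
    start_s: float = 0.0  # offset of the analysis window into the recording
    q_level: float = 0.05
    t_variant: str = "student"
    psd_f_start: float = 5.0
    psd_f_stop: float = 60.0
    psd_bin_width: float = 1.0
    welch: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trim_s < 0 or 2 * self.trim_s >= self.epoch_s:
            raise InputError("need 0 <= 2*trim_s < epoch_s")
        if self.start_s < 0:
            raise InputError("start_s must be >= 0")

    def resolve_bands(self, fs: float) -> tuple[BandScaleRange, ...]:
        return tuple(default_band_table(fs)) if self.bands is None else self.bands

    @staticmethod
    def band_from_dict(d: dict, fs: float) -> BandScaleRange:
        if "k_min" in d and "k_max" in d:
            return BandScaleRange(
                label=d.get("label", "custom"),
                f_low=float(d.get("f_low", fs / d["k_max"])),
                f_high=float(d.get("f_high", fs / d["k_min"])),
                k_min=int(d["k_min"]),
                k_max=int(d["k_max"]),
                narrow=(int(d["k_max"]) - int(d["k_min"])) < 10,
                override=True,
            )
        return band_to_scales(fs, float(d["f_low"]), float(d["f_high"]), d.get("label", ""))

    @classmethod
    def from_json(cls, path: str | Path, fs: float) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        bands = raw.pop("bands", None)
        if bands is not None:
            raw["bands"] = tuple(cls.band_from_dict(b, fs) for b in bands)
        return cls(**raw)


def prepare_epoch(recording: Recording, config: RunConfig) -> Recording:
    """``epoch_s`` window starting at ``start_s`` with ``trim_s`` removed
    from each end.

    At the defaults (leading 60 s epoch, 5 s trim, 200 Hz) every channel ends
    up with exactly 10,000 samples.  ``start_s`` lets the caller pick a later
    window in longer recordings; programmatic artifact screening is out of
    scope, so window choice (like subject inclusion) rests with the user.
    """
    end_s = config.start_s + config.epoch_s
    if recording.n_samples < int(round(end_s * recording.fs)):
        raise InputError(
            f"recording {recording.subject_id!r} shorter than the "
            f"{config.epoch_s} s analysis epoch at offset {config.start_s} s"
        )
    chans = tuple(
        ch.slice_seconds(config.start_s, end_s).slice_seconds(
            config.trim_s, config.epoch_s - config.trim_s
        )
        for ch in recording.channels
    )
    return Recording(chans, recording.subject_id, recording.group, recording.covariate)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_cohort_dir(
    path: str | Path, fs: float, include: list[str] | None = None
) -> list[Recording]:
    """Load a cohort directory: ``meta.tsv`` plus one delimited matrix per
    subject.

    ``include`` restricts loading to the listed subject ids — the explicit
    replacement for visual artifact screening, which is out of scope.
    """
    path = Path(path)
    meta = pd.read_csv(path / "meta.tsv", sep="\t")
    if include is not None:
        missing = set(include) - set(meta["subject"].astype(str))
        if missing:
            raise InputError(f"inclusion list names unknown subjects: {sorted(missing)}")
        meta = meta[meta["subject"].astype(str).isin(include)]
    recs = []
    for row in meta.itertuples():
        f = path / f"{row.subject}.tsv"
        rec = read_recording(f, fmt="delimited", fs=fs)
        recs.append(
            Recording(
                rec.channels,
                subject_id=str(row.subject),
                group=str(row.group),
                covariate=float(row.covariate) if hasattr(row, "covariate") else None,
            )
        )
    return recs


@dataclass
class RunResult:
    """Bundle of everything one analysis run produces."""

    cohort: CohortTable
    dimensions: pd.DataFrame          # subject, channel, band, D
    psd_table: pd.DataFrame           # subject, channel, freq, power_db
    ttests: dict[str, list[TestResult]]
    anovas: dict[str, RmAnovaResult]
    correlations: dict[str, list[TestResult]]
    exclusions: list[dict]
    run_log: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> Path:
        """Write all tables as TSV plus the JSON run log; returns the directory."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fmt = lambda df: df.to_csv(float_format="%.6g", sep="\t", index=False)
        (out / "dimensions.tsv").write_text(fmt(self.dimensions))
        (out / "psd.tsv").write_text(fmt(self.psd_table))
        rows = [
            {"band": band, "channel": r.effect, "t": r.statistic, "p": r.p, "q": r.q}
            for band, rs in self.ttests.items()
            for r in rs
        ]
        (out / "ttests.tsv").write_text(fmt(pd.DataFrame(rows)))
        rows = []
        for band, res in self.anovas.items():
            for eff in (res.group, res.interaction):
                rows.append(
                    {"band": band, "effect": eff.effect, "F": eff.statistic,
                     "df1": eff.df[0], "df2": eff.df[1], "p": eff.p,
                     "gg_epsilon": res.epsilon}
                )
        (out / "anova.tsv").write_text(fmt(pd.DataFrame(rows)))
        rows = [
            {"band": band, "channel": r.effect, "r": r.statistic, "p": r.p}
            for band, rs in self.correlations.items()
            for r in rs
        ]
        (out / "correlations.tsv").write_text(fmt(pd.DataFrame(rows)))
        (out / "run_log.json").write_text(json.dumps(self.run_log, indent=2, sort_keys=True))
        return out


def run_analysis(
    recordings: list[Recording],
    config: RunConfig | None = None,
    input_paths: list[Path] | None = None,
) -> RunResult:
    """Run the full analysis on a cohort of recordings.

    Per-subject failures are logged and the subject excluded; the run fails
    only if a group drops below 2 subjects.  Fractal dimensions are estimated
    on the trimmed epoch, PSDs on the untrimmed leading epoch, group tests on
    log-transformed dimensions with BH families of 16 (entire band), 48
    (three specific bands pooled) and 56 x channels for the PSD grid.
    """
    config = config or RunConfig()
    if not recordings:
        raise InputError("empty cohort")
    fs = recordings[0].fs
    bands = config.resolve_bands(fs)

    dim_rows, psd_rows, exclusions = [], [], []
    meta_rows = []
    for rec in recordings:
        try:
            end_s = config.start_s + config.epoch_s
            if rec.n_samples < int(round(end_s * rec.fs)):
                raise InputError("recording shorter than the analysis epoch")
            full = Recording(
                tuple(ch.slice_seconds(config.start_s, end_s) for ch in rec.channels),
                rec.subject_id, rec.group, rec.covariate,
            )
            trimmed = prepare_epoch(rec, config)
            sub_dims, sub_psd = [], []
            for ch_full, ch_trim in zip(full.channels, trimmed.channels):
                for band in bands:
                    est = scale_specific_dimension(ch_trim, band)
                    sub_dims.append(
                        {"subject": rec.subject_id, "channel": ch_trim.label,
                         "band": band.label, "D": est.dimension,
                         "r_squared": est.r_squared}
                    )
                spec = psd(ch_full, mode="welch" if config.welch else "single")
                binned = bin_psd(spec, config.psd_f_start, config.psd_f_stop, config.psd_bin_width)
                for f, db in zip(binned.freqs, binned.power_db):
                    sub_psd.append(
                        {"subject": rec.subject_id, "channel": ch_full.label,
                         "freq": f, "power_db": db}
                    )
        except ScaleFDError as exc:
            exclusions.append({"subject": rec.subject_id, "reason": str(exc)})
            continue
        dim_rows.extend(sub_dims)
        psd_rows.extend(sub_psd)
        meta_rows.append(
            {"subject": rec.subject_id, "group": rec.group, "covariate": rec.covariate}
        )

    meta = pd.DataFrame(meta_rows)
    if meta.empty or meta["group"].nunique() != 2 or (meta["group"].value_counts() < 2).any():
        raise InputError(
            f"fewer than 2 analyzable subjects in a group; exclusions: {exclusions}"
        )
    dimensions = pd.DataFrame(dim_rows)
    cohort = CohortTable(
        data=dimensions[["subject", "channel", "band", "D"]], meta=meta
    )
    logged = log_transform(cohort)

    band_labels = [b.label for b in bands]
    specific = [b for b in band_labels if b != "entire"]
    ttests: dict[str, list[TestResult]] = {}
    if "entire" in band_labels:
        ttests["entire"] = attach_fdr(
            sensorwise_ttests(logged, "entire", config.t_variant), config.q_level
        )
    if specific:
        pooled: list[TestResult] = []
        spans: list[tuple[str, int]] = []
        for band in specific:
            rs = sensorwise_ttests(logged, band, config.t_variant)
            spans.append((band, len(rs)))
            pooled.extend(rs)
        pooled = attach_fdr(pooled, config.q_level)  # family = bands x channels
        i = 0
        for band, span in spans:
            ttests[band] = pooled[i : i + span]
            i += span

    anovas = {band: rm_anova(logged, band) for band in band_labels}

    correlations: dict[str, list[TestResult]] = {}
    if meta.get("covariate") is not None and meta["covariate"].notna().all():
        for band in band_labels:
            try:
                correlations[band] = covariate_correlation(cohort, band)
            except InputError:
                break  # too few subjects or constant covariate: skip the block

    psd_table = pd.DataFrame(psd_rows)

    run_log = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config": {
            k: v for k, v in asdict(config).items() if k != "bands"
        },
        "bands": [
            {"label": b.label, "f_low": b.f_low, "f_high": b.f_high,
             "k_min": b.k_min, "k_max": b.k_max, "override": b.override}
            for b in bands
        ],
        "n_subjects_in": len(recordings),
        "n_subjects_analyzed": int(meta.shape[0]),
        "n_subjects_excluded": len(exclusions),
        "input_checksums": {
            str(p): _sha256(Path(p)) for p in (input_paths or [])
        },
    }
    return RunResult(
        cohort=cohort,
        dimensions=dimensions,
        psd_table=psd_table,
        ttests=ttests,
        anovas=anovas,
        correlations=correlations,
        exclusions=exclusions,
        run_log=run_log,
    )
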