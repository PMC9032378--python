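"""End-to-end pipeline: simulate -> extract -> classify -> map -> analyze.

Each stage persists plain CSV/JSON intermediates so any stage can be re-run
or inspected independently; a manifest records the config hash, seed,
package versions and per-stage row counts.  Identical config + seed
reproduce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classification import ClassificationConfig, classify_trace
from .extraction import ExtractionConfig, extract_trace, read_buffers_csv
from .outcomes import CohortOutcomeModel, hearing_loss
from .placemap import InsertionGeometry, estimate_cf
from .synthetic import CohortConfig, generate_cohort, read_audiograms_csv, write_cohort

log = logging.getLogger("ecochg")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one reproducible pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    classification: ClassificationConfig = field(default_factory=ClassificationConfig)
    cf_table_path: str | None = None
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        def build(klass, section):
            known = {f.name for f in fields(klass)}
            unknown = set(section) - known
            if unknown:
                raise ValueError(f"unknown {klass.__name__} keys: {sorted(unknown)}")
            coerced = {}
            for f in fields(klass):
                if f.name in section:
                    value = section[f.name]
                    coerced[f.name] = tuple(value) if isinstance(value, list) else value
            return klass(**coerced)

        seed = int(raw.get("seed", 0))
        cohort_section = dict(raw.get("cohort", {}))
        cohort_section.setdefault("seed", seed)
        return cls(
            cohort=build(CohortConfig, cohort_section),
            extraction=build(ExtractionConfig, raw.get("extraction", {})),
            classification=build(ClassificationConfig, raw.get("classification", {})),
            cf_table_path=raw.get("cf_table_path"),
            seed=seed,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return {
            "cohort": asdict(self.cohort),
            "extraction": asdict(self.extraction),
            "classification": asdict(self.classification),
            "cf_table_path": self.cf_table_path,
            "seed": self.seed,
        }


def _config_hash(config: RunConfig) -> str:
    canonical = json.dumps(config.to_dict(), sort_keys=True, default=list)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def stage_simulate(config: RunConfig, out_dir: Path) -> int:
    records = generate_cohort(config.cohort)
    write_cohort(records, out_dir)
    log.info("simulate: %d subjects written", len(records))
    return len(records)


def stage_extract(config: RunConfig, in_dir: Path, out_path: Path) -> int:
    frames = []
    for path in sorted((Path(in_dir) / "buffers").glob("*.csv")):
        buffers = read_buffers_csv(path)
        trace = extract_trace(buffers, config.extraction, subject_id=path.stem)
        frames.append(trace.to_dataframe())
    if not frames:
        raise FileNotFoundError(f"no buffer CSVs under {in_dir}/buffers")
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(out_path, index=False, float_format="%.6g")
    log.info("extract: %d points from %d subjects", len(df), len(frames))
    return len(df)


def stage_classify(config: RunConfig, traces_path: Path, out_path: Path) -> int:
    from .extraction import InsertionTrace

    df = pd.read_csv(traces_path)
    rows = []
    for subject_id, sub in df.groupby("subject_id", sort=True):
        trace = InsertionTrace.from_dataframe(sub)
        rows.append({"subject_id": subject_id, **classify_trace(trace, config.classification)})
    out = pd.DataFrame(rows)
    out.to_csv(out_path, index=False, float_format="%.6g")
    excluded = int((out["pattern_group"] == "no_response").sum())
    log.info(
        "classify: %d subjects, %d with measurable CM, %d no-response excluded",
        len(out),
        len(out) - excluded,
        excluded,
    )
    return len(out)


def stage_cf(config: RunConfig, truth_path: Path, out_path: Path) -> int:
    with open(truth_path) as fh:
        truth = json.load(fh)
    rows = []
    for subject_id in sorted(truth):
        est = estimate_cf(
            InsertionGeometry(angle_deg=truth[subject_id]["insertion_angle_deg"]),
            table_path=config.cf_table_path,
        )
        rows.append(
            {
                "subject_id": subject_id,
                "insertion_angle_deg": truth[subject_id]["insertion_angle_deg"],
                "cf_hz": est.cf_hz,
                "fractional_length_from_base": est.fractional_length_from_base,
                "cf_passed": est.cf_passed,
            }
        )
    pd.DataFrame(rows).to_csv(out_path, index=False, float_format="%.6g")
    log.info("cf: %d subjects mapped", len(rows))
    return len(rows)


def build_cohort_table(classes_path: Path, audiograms_path: Path) -> pd.DataFrame:
    """Join classification features with audiometric outcomes per subject."""
    classes = pd.read_csv(classes_path)
    audiograms = read_audiograms_csv(audiograms_path)
    rows = []
    for _, row in classes.iterrows():
        subject_id = str(row["subject_id"])
        pair = audiograms.get(subject_id, {})
        rec = dict(row)
        if "pre" in pair and "post4w" in pair:
            hl = hearing_loss(pair["pre"], pair["post4w"])
            rec["lf_hl"] = hl.lf_pta_hl
            rec["preop_lf_pta_db"] = pair["pre"].lf_pta()
            rec["preop_500_db"] = float(pair["pre"].as_array()[2])
        rows.append(rec)
    return pd.DataFrame(rows)


def stage_analyze(config: RunConfig, classes_path: Path, audiograms_path: Path, out_dir: Path) -> int:
    table = build_cohort_table(classes_path, audiograms_path)
    results = CohortOutcomeModel.from_dataframe(table).fit()
    report = results.to_dict()
    report["seed"] = config.seed
    with open(Path(out_dir) / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    with open(Path(out_dir) / "report.txt", "w") as fh:
        fh.write(results.summary() + "\n")
    log.info("analyze: %d subjects, %d analyzed", results.n_subjects, results.n_analyzed)
    return results.n_analyzed


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Execute all stages in order; returns the run directory.

    Any stage failure aborts with an error naming the stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    stages = [
        ("simulate", lambda: stage_simulate(config, out)),
        ("extract", lambda: stage_extract(config, out, out / "traces.csv")),
        ("classify", lambda: stage_classify(config, out / "traces.csv", out / "classes.csv")),
        ("cf", lambda: stage_cf(config, out / "truth.json", out / "cf.csv")),
        (
            "analyze",
            lambda: stage_analyze(config, out / "classes.csv", out / "audiograms.csv", out),
        ),
    ]
    for name, func in stages:
        try:
            counts[name] = func()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
    manifest = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "versions": {"ecochg": __version__},
        "stage_rows": counts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=list)
    return out
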