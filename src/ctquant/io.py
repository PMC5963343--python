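"""Tabular input/output: Ct tables, sample metadata, reports, config files.

All tables are comma-separated UTF-8 with a required header row and "."
as the decimal mark (a tab-separated variant is accepted via ``sep``).
Undetected wells may be written as ``Undetermined``, ``NA`` or an empty
field; they round-trip to ``ct=None``.
"""
from __future__ import annotations

import hashlib
import logging
import math
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .datamodel import (
    AssayPanel,
    CtMeasurement,
    SampleRecord,
    Thresholds,
    check_unique_measurements,
)
from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Tokens interpreted as "well did not cross the detection threshold".
UNDETECTED_TOKENS = {"", "undetermined", "na", "nan", "undetected"}

_CT_COLUMNS = ["sample_id", "assay", "run_id", "replicate", "ct"]
_SAMPLE_COLUMNS = [
    "sample_id", "subject_id", "cohort_arm", "tissue", "group",
    "age_years", "sex", "age_at_onset_years", "disease_duration_years",
    "post_mortem_time_hours", "rin",
]
_SAMPLE_REQUIRED = ["sample_id", "tissue", "group", "age_years"]


def _read_csv(path, sep: str = ",") -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise FormatError(f"{path}: cannot parse as CSV ({exc})") from exc


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")


def _parse_float(token: str, path, col: str, row: int) -> float | None:
    token = token.strip()
    if token.lower() in UNDETECTED_TOKENS:
        return None
    # locale-independent: "." decimal mark only, no thousands separators
    if "," in token:
        raise FormatError(
            f"{path} row {row}: {col}={token!r} uses a comma; decimal point required"
        )
    try:
        return float(token)
    except ValueError as exc:
        raise FormatError(f"{path} row {row}: cannot parse {col}={token!r}") from exc


def read_ct_table(path, sep: str = ",") -> list[CtMeasurement]:
    """Read a long-format Ct table into validated measurements.

    Expected columns: sample_id, assay, run_id, replicate, ct.  Duplicate
    (sample, assay, run, replicate) keys are rejected.
    """
    df = _read_csv(path, sep=sep)
    _require_columns(df, _CT_COLUMNS, path)
    out: list[CtMeasurement] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            rep = int(str(row.replicate).strip())
        except ValueError as exc:
            raise FormatError(
                f"{path} row {i}: replicate={row.replicate!r} is not an integer"
            ) from exc
        out.append(CtMeasurement(
            sample_id=str(row.sample_id).strip(),
            assay=str(row.assay).strip(),
            run_id=str(row.run_id).strip(),
            replicate_index=rep,
            ct=_parse_float(str(row.ct), path, "ct", i),
        ))
    check_unique_measurements(out)
    return out


def write_ct_table(measurements: Iterable[CtMeasurement], path, sep: str = ",") -> None:
    """Write measurements in the long format :func:`read_ct_table` reads."""
    rows = [
        {
            "sample_id": m.sample_id,
            "assay": m.assay,
            "run_id": m.run_id,
            "replicate": m.replicate_index,
            "ct": "Undetermined" if m.ct is None else repr(m.ct),
        }
        for m in measurements
    ]
    pd.DataFrame(rows, columns=_CT_COLUMNS).to_csv(path, sep=sep, index=False)


def read_sample_metadata(path, sep: str = ",") -> list[SampleRecord]:
    """Read sample metadata into validated :class:`SampleRecord` objects.

    Columns beyond the known ones are ignored with a logged warning;
    optional covariates may be blank or ``NA``.
    """
    df = _read_csv(path, sep=sep)
    _require_columns(df, _SAMPLE_REQUIRED, path)
    unknown = [c for c in df.columns if c not in _SAMPLE_COLUMNS]
    if unknown:
        logger.warning("%s: ignoring unknown column(s): %s", path, ", ".join(unknown))

    def get(row: dict, col: str) -> str:
        return str(row.get(col, "")).strip()

    out: list[SampleRecord] = []
    for i, raw in enumerate(df.to_dict(orient="records"), start=2):
        sample_id = get(raw, "sample_id")
        tissue = get(raw, "tissue")
        arm = get(raw, "cohort_arm") or ("blood" if tissue == "blood" else "brain")
        sex = get(raw, "sex") or "unknown"
        out.append(SampleRecord(
            sample_id=sample_id,
            subject_id=get(raw, "subject_id") or sample_id,
            cohort_arm=arm,
            tissue=tissue,
            group=get(raw, "group"),
            age_years=_parse_float(get(raw, "age_years"), path, "age_years", i),
            sex=sex,
            age_at_onset_years=_parse_float(
                get(raw, "age_at_onset_years"), path, "age_at_onset_years", i),
            disease_duration_years=_parse_float(
                get(raw, "disease_duration_years"), path, "disease_duration_years", i),
            post_mortem_time_hours=_parse_float(
                get(raw, "post_mortem_time_hours"), path, "post_mortem_time_hours", i),
            rin=_parse_float(get(raw, "rin"), path, "rin", i),
        ))
    ids = [s.sample_id for s in out]
    if len(set(ids)) != len(ids):
        dupes = sorted({x for x in ids if ids.count(x) > 1})
        raise ValidationError(f"{path}: duplicate sample_id(s): {', '.join(dupes)}")
    return out


def write_sample_metadata(samples: Iterable[SampleRecord], path, sep: str = ",") -> None:
    """Write sample metadata in the format :func:`read_sample_metadata` reads."""
    def fmt(v):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return ""
        return repr(v) if isinstance(v, float) else v

    rows = [
        {
            "sample_id": s.sample_id,
            "subject_id": s.subject_id,
            "cohort_arm": s.cohort_arm,
            "tissue": s.tissue,
            "group": s.group,
            "age_years": fmt(float(s.age_years)),
            "sex": s.sex,
            "age_at_onset_years": fmt(s.age_at_onset_years),
            "disease_duration_years": fmt(s.disease_duration_years),
            "post_mortem_time_hours": fmt(s.post_mortem_time_hours),
            "rin": fmt(s.rin),
        }
        for s in samples
    ]
    pd.DataFrame(rows, columns=_SAMPLE_COLUMNS).to_csv(path, sep=sep, index=False)


def write_report(
    profile: pd.DataFrame,
    comparisons: pd.DataFrame | None,
    out_dir,
    seed: int | None = None,
    config: dict | None = None,
) -> dict[str, Path]:
    """Write the expression profile, stratified comparisons and a run log.

    The data CSVs are deterministic (byte-identical on rerun with the
    same inputs); the log records the seed and a SHA-256 hash of the
    configuration for provenance.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create report directory {out_dir}: {exc}") from exc
    paths = {}
    profile_path = out_dir / "expression_profile.csv"
    profile.to_csv(profile_path, index=False)
    paths["profile"] = profile_path
    strata_path = out_dir / "stratified_comparisons.csv"
    if comparisons is None:
        comparisons = pd.DataFrame()
    comparisons.to_csv(strata_path, index=False)
    paths["comparisons"] = strata_path
    log_path = out_dir / "run_log.txt"
    cfg_hash = config_hash(config or {})
    log_path.write_text(
        "ctquant report\n"
        f"seed: {seed if seed is not None else 'not set'}\n"
        f"config_sha256: {cfg_hash}\n"
        f"profile_rows: {len(profile)}\n"
        f"comparison_rows: {len(comparisons)}\n",
        encoding="utf-8",
    )
    paths["log"] = log_path
    return paths


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def config_hash(config: dict) -> str:
    """Stable SHA-256 of a configuration mapping."""
    canon = yaml.safe_dump(config, sort_keys=True, default_flow_style=True)
    return hashlib.sha256(canon.encode("utf-8")).hexdigest()


def load_config(path) -> dict:
    """Load a YAML config with optional panel/thresholds/simulation sections."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg


def panel_from_config(cfg: dict) -> AssayPanel | None:
    sec = cfg.get("panel")
    if not sec:
        return None
    return AssayPanel(
        targets=tuple(sec.get("targets", ())),
        references=tuple(sec.get("references", ())),
        amplicon_size_bp=dict(sec.get("amplicon_size_bp", {})),
    )


def thresholds_from_config(cfg: dict) -> Thresholds:
    sec = cfg.get("thresholds", {})
    return Thresholds(
        decrease_threshold=float(sec.get("decrease", 0.5)),
        increase_threshold=float(sec.get("increase", 1.5)),
        efficiency_tolerance=float(sec.get("efficiency_tolerance", 0.1)),
    )
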