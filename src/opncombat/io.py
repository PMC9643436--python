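"""CSV ingest/egress for feature tables and sample metadata.

External files are plain UTF-8 CSVs with a header row, samples as rows,
and a schema that names the sample-ID column and assigns every other
metadata column a role: ``batch``, ``categorical_covariate``,
``continuous_covariate``, ``time``, ``event`` or ``ignore``.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .data import FeatureMatrix, SampleMetadata, ValidationError
from .nested import HarmonizationReport

logger = logging.getLogger(__name__)

__all__ = ["read_dataset", "write_outputs"]

ROLES = {"batch", "categorical_covariate", "continuous_covariate",
         "time", "event", "ignore"}


def read_dataset(
    features_path: str | Path,
    metadata_path: str | Path,
    schema: dict,
    missing_policy: str = "error",
) -> tuple[FeatureMatrix, SampleMetadata]:
    """Read and join a feature CSV and a metadata CSV.

    ``schema`` maps ``sample_id`` to the ID column name and ``roles`` to a
    column -> role mapping for the metadata file. Samples present in only
    one file are dropped with a warning. ``missing_policy`` controls
    missing feature cells: ``"error"`` (default) or ``"drop_features"``.
    """
    id_col = schema.get("sample_id")
    if not id_col:
        raise ValidationError("schema must name the sample_id column")
    roles: dict = schema.get("roles", {})
    bad_roles = {r for r in roles.values() if r not in ROLES}
    if bad_roles:
        raise ValidationError(f"unknown roles in schema: {sorted(bad_roles)}")

    feat = pd.read_csv(features_path)
    meta = pd.read_csv(metadata_path)
    for name, df in (("features", feat), ("metadata", meta)):
        if id_col not in df.columns:
            raise ValidationError(f"{name} file has no column {id_col!r}")
        if df[id_col].duplicated().any():
            dups = df[id_col][df[id_col].duplicated()].tolist()
            raise ValidationError(f"duplicate sample IDs in {name}: {dups}")
    feat = feat.set_index(id_col)
    meta = meta.set_index(id_col)

    common = feat.index.intersection(meta.index)
    dropped = set(feat.index.symmetric_difference(meta.index))
    if dropped:
        logger.warning(
            "%d sample(s) present in only one file dropped: %s",
            len(dropped), sorted(map(str, dropped))[:10],
        )
    feat = feat.loc[common]
    meta = meta.loc[common]

    if feat.isna().any().any():
        if missing_policy == "drop_features":
            bad = feat.columns[feat.isna().any()].tolist()
            logger.warning(
                "dropping %d feature(s) with missing values: %s",
                len(bad), bad[:10],
            )
            feat = feat.drop(columns=bad)
        else:
            col = feat.columns[feat.isna().any()][0]
            sid = feat.index[feat[col].isna()][0]
            raise ValidationError(
                f"missing feature value at sample {sid!r}, feature {col!r}; "
                "pass missing_policy='drop_features' to drop such features"
            )

    features = FeatureMatrix(feat)
    metadata = SampleMetadata(
        meta,
        batch_vars=[c for c, r in roles.items() if r == "batch"],
        categorical_covariates=[
            c for c, r in roles.items() if r == "categorical_covariate"
        ],
        continuous_covariates=[
            c for c, r in roles.items() if r == "continuous_covariate"
        ],
        time_col=next((c for c, r in roles.items() if r == "time"), None),
        event_col=next((c for c, r in roles.items() if r == "event"), None),
    )
    return features, metadata


def write_outputs(
    harmonized: FeatureMatrix,
    report: HarmonizationReport | None,
    out_dir: str | Path,
    id_col: str = "sample_id",
) -> dict[str, Path]:
    """Write the harmonized matrix (CSV) and the run report (JSON)."""
    if report is None:
        raise ValidationError("no harmonization report to write")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    feat_path = out / "harmonized_features.csv"
    harmonized.values.rename_axis(id_col).reset_index().to_csv(
        feat_path, index=False, float_format="%.17g"
    )
    report_path = out / "report.json"
    report_path.write_text(json.dumps(report.to_dict(), indent=2))
    logger.info("wrote %s and %s", feat_path, report_path)
    return {"features": feat_path, "report": report_path}
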