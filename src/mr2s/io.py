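"""Reading, writing and harmonizing GWAS summary-statistics tables.

Tables are tab-separated text with a header row; a :class:`ColumnDialect`
maps the canonical field names (snp, chr, pos, ea, eaf, beta, se, pval) onto
whatever the file's columns are called. The bundled 52-instrument BMI/T2DM
fixture ships in :mod:`mr2s.data` together with its handling policy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml
from scipy import stats

from .records import (
    ConfigError,
    EmptyIntersectionError,
    ValidationError,
    HarmonizedInstrument,
    VariantAssociation,
)

log = logging.getLogger(__name__)

#: rsIDs of the known BMI loci also associated with the outcome in prior
#: meta-analysis; excluded from the instrument set by default.
KNOWN_OUTCOME_LOCI_FILE = "known_t2dm_loci.txt"
TABLE1_FILE = "bmi_t2dm_table1.tsv"
TABLE1_METADATA_FILE = "table1_metadata.yaml"


@dataclass(slots=True)
class ColumnDialect:
    """Maps canonical field names to column headers of a summary table.

    ``snp``, ``beta``, ``se`` and ``pval`` are mandatory; the rest are used
    when present. Load from YAML with :meth:`from_yaml` (keys: snp, chr, pos,
    ea, eaf, beta, se, pval, gene).
    """

    snp: str
    beta: str
    se: str
    pval: str
    chr: str | None = None
    pos: str | None = None
    ea: str | None = None
    eaf: str | None = None
    gene: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ColumnDialect":
        with open(path) as fh:
            mapping = yaml.safe_load(fh)
        return cls.from_mapping(mapping)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "ColumnDialect":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown dialect keys: {sorted(unknown)}")
        missing = {"snp", "beta", "se", "pval"} - set(mapping)
        if missing:
            raise ConfigError(f"dialect missing mandatory keys: {sorted(missing)}")
        return cls(**mapping)

    def mapped(self) -> dict[str, str]:
        """Canonical-name -> column-header for all mapped fields."""
        return {
            f: getattr(self, f)
            for f in self.__dataclass_fields__
            if getattr(self, f) is not None
        }


def _parse_float(raw: object) -> float | None:
    try:
        v = float(str(raw).strip())
    except (TypeError, ValueError):
        return None
    return v if math.isfinite(v) else None


def _parse_pos(raw: object) -> int | None:
    # positions are sometimes printed with thousands separators ("59,159,129")
    s = str(raw).strip().replace(",", "")
    try:
        return int(s)
    except ValueError:
        return None


def read_summary_table(
    path: str | Path, dialect: ColumnDialect
) -> list[VariantAssociation]:
    """Read one trait's associations from a tab-separated summary table.

    Rows with an unparseable beta are kept with ``beta_missing`` set, so the
    caller can decide between imputation and exclusion. Raises
    :class:`ConfigError` if a mapped column is absent from the header and
    :class:`ValidationError` for a non-positive SE (naming the SNP).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for field_name, column in dialect.mapped().items():
        if column not in df.columns:
            raise ConfigError(
                f"column {column!r} (mapped to {field_name!r}) not in header of {path}"
            )
    records: list[VariantAssociation] = []
    for _, row in df.iterrows():
        snp = str(row[dialect.snp]).strip()
        beta = _parse_float(row[dialect.beta])
        se = _parse_float(row[dialect.se])
        if se is None or se <= 0:
            raise ValidationError(f"non-positive or missing SE for SNP {snp}")
        pval = _parse_float(row[dialect.pval])
        if pval is None:
            raise ValidationError(f"unparseable P-value for SNP {snp}")
        pos = _parse_pos(row[dialect.pos]) if dialect.pos else None
        records.append(
            VariantAssociation(
                snp_id=snp,
                chrom=str(row[dialect.chr]).strip() if dialect.chr else "",
                pos=pos,
                gene=str(row[dialect.gene]).strip() if dialect.gene else "",
                effect_allele=(
                    str(row[dialect.ea]).strip().upper() or None
                    if dialect.ea
                    else None
                ),
                eaf=_parse_float(row[dialect.eaf]) if dialect.eaf else None,
                beta=beta,
                se=se,
                pval=pval,
                beta_missing=beta is None,
            )
        )
    return records


def write_summary_table(
    records: list[VariantAssociation], path: str | Path, dialect: ColumnDialect
) -> None:
    """Write records as a tab-separated table using ``dialect`` headers.

    Numeric fields are written with 10 significant digits so that a
    read/write cycle round-trips beyond 6 significant digits.
    """
    cols = dialect.mapped()
    rows = []
    for rec in records:
        row = {
            cols["snp"]: rec.snp_id,
            cols["beta"]: "" if rec.beta is None else f"{rec.beta:.10g}",
            cols["se"]: f"{rec.se:.10g}",
            cols["pval"]: f"{rec.pval:.10g}",
        }
        if "chr" in cols:
            row[cols["chr"]] = rec.chrom
        if "pos" in cols:
            row[cols["pos"]] = "" if rec.pos is None else str(rec.pos)
        if "gene" in cols:
            row[cols["gene"]] = rec.gene
        if "ea" in cols:
            row[cols["ea"]] = rec.effect_allele or ""
        if "eaf" in cols:
            row[cols["eaf"]] = "" if rec.eaf is None else f"{rec.eaf:.10g}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def impute_missing_beta(v: VariantAssociation, sign: int) -> VariantAssociation:
    """Reconstruct an unreported beta from its SE and two-sided P-value.

    |beta| = se * z with z the upper-(pval/2) standard-normal quantile, signed
    by ``sign``; P = 1 gives beta = 0 exactly. Returns a new record with
    ``beta_missing`` cleared.
    """
    if not v.beta_missing:
        raise ValidationError(f"SNP {v.snp_id}: beta is not missing, nothing to impute")
    if v.se is None:
        raise ValidationError(f"SNP {v.snp_id}: cannot impute beta without SE")
    if sign not in (-1, 1):
        raise ConfigError(f"imputation sign must be +1 or -1, got {sign}")
    z = 0.0 if v.pval >= 1.0 else float(stats.norm.isf(v.pval / 2.0))
    beta = sign * v.se * z
    log.info(
        "imputed beta for %s: sign=%+d, se=%g, p=%g -> beta=%g",
        v.snp_id, sign, v.se, v.pval, beta,
    )
    return replace(v, beta=beta, beta_missing=False)


def harmonize_pair(
    exposure: list[VariantAssociation], outcome: list[VariantAssociation]
) -> list[HarmonizedInstrument]:
    """Inner-join exposure and outcome associations on rsID onto one allele.

    Where both records carry an effect allele and they differ
    (case-insensitively), the outcome beta sign is flipped and
    ``orientation_flipped`` set. SNPs present in only one dataset are dropped
    and logged. Records still flagged ``beta_missing`` are rejected: impute
    or exclude them first.
    """
    out_by_id = {v.snp_id: v for v in outcome}
    shared = [v for v in exposure if v.snp_id in out_by_id]
    if not shared:
        raise EmptyIntersectionError("exposure and outcome tables share no SNPs")
    for v in exposure:
        if v.snp_id not in out_by_id:
            log.info("dropping %s: absent from outcome table", v.snp_id)
    exp_ids = {v.snp_id for v in exposure}
    for v in outcome:
        if v.snp_id not in exp_ids:
            log.info("dropping %s: absent from exposure table", v.snp_id)

    instruments: list[HarmonizedInstrument] = []
    for ev in shared:
        ov = out_by_id[ev.snp_id]
        for v, role in ((ev, "exposure"), (ov, "outcome")):
            if v.beta_missing or v.beta is None:
                raise ValidationError(
                    f"SNP {v.snp_id}: missing {role} beta; impute or exclude before harmonizing"
                )
        flip = (
            ev.effect_allele is not None
            and ov.effect_allele is not None
            and ev.effect_allele.upper() != ov.effect_allele.upper()
        )
        instruments.append(
            HarmonizedInstrument(
                snp_id=ev.snp_id,
                beta_exposure=ev.beta,
                se_exposure=ev.se,
                beta_outcome=-ov.beta if flip else ov.beta,
                se_outcome=ov.se,
                pval_exposure=ev.pval,
                pval_outcome=ov.pval,
                chrom=ev.chrom,
                pos=ev.pos or 0,
                gene=ev.gene,
                orientation_flipped=flip,
            )
        )
    return instruments


def _data_path(name: str):
    return resources.files("mr2s").joinpath("data", name)


def load_table1_metadata() -> dict:
    """Handling policy and provenance notes for the bundled fixture."""
    with _data_path(TABLE1_METADATA_FILE).open() as fh:
        return yaml.safe_load(fh)


def load_known_outcome_loci() -> list[str]:
    """The bundled default exclusion list of outcome-associated loci."""
    with _data_path(KNOWN_OUTCOME_LOCI_FILE).open() as fh:
        return [line.strip() for line in fh if line.strip()]


def load_table1(
    path: str | Path | None = None,
) -> tuple[list[VariantAssociation], list[VariantAssociation]]:
    """Load the bundled merged BMI/T2DM table as (exposure, outcome) records."""
    meta = load_table1_metadata()
    exp_dialect = ColumnDialect.from_mapping(meta["exposure_columns"])
    out_dialect = ColumnDialect.from_mapping(meta["outcome_columns"])
    src = path if path is not None else _data_path(TABLE1_FILE)
    return (
        read_summary_table(src, exp_dialect),
        read_summary_table(src, out_dialect),
    )


def load_table1_instruments(
    missing_beta: str | None = None, impute_sign: int | None = None
) -> list[HarmonizedInstrument]:
    """The bundled 52-SNP BMI -> T2DM instrument set, harmonized.

    ``missing_beta`` is ``"impute"`` (default, per the bundled policy: the one
    unreported outcome beta is reconstructed from its SE and P with
    ``impute_sign``) or ``"exclude"``.
    """
    meta = load_table1_metadata()
    policy = meta["missing_outcome_beta"]
    missing_beta = missing_beta or policy["policy"]
    impute_sign = impute_sign if impute_sign is not None else int(policy["sign"])
    exposure, outcome = load_table1()
    if missing_beta == "impute":
        outcome = [
            impute_missing_beta(v, impute_sign) if v.beta_missing else v
            for v in outcome
        ]
    elif missing_beta == "exclude":
        dropped = {v.snp_id for v in outcome if v.beta_missing}
        exposure = [v for v in exposure if v.snp_id not in dropped]
        outcome = [v for v in outcome if not v.beta_missing]
    else:
        raise ConfigError(
            f"missing_beta policy must be 'impute' or 'exclude', got {missing_beta!r}"
        )
    return harmonize_pair(exposure, outcome)
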