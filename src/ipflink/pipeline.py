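"""End-to-end runs: configuration, attrition logging, report bundle.

A run reads the five input tables and two codelists, links them, applies the
study eligibility filter, fits a :class:`~ipflink.validation.ValidationStudy`
over the requested algorithms, and writes delimited reports plus a
machine-readable manifest (config hash and per-stage row counts). One run
writes one immutable output directory; inputs are never modified.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import pandas as pd

from .casefinding import ALGORITHM_PRESETS, DeathCauseMode, link_cohort
from .descriptive import code_usage_by_year, noncordant_death_causes
from .eligibility import StudyConfig, is_study_eligible
from .errors import ConfigurationError
from .io import read_codelist, read_table
from .validation import ValidationStudy, round_pct

__all__ = ["RunConfig", "ReportBundle", "run_full_validation"]

log = logging.getLogger("ipflink")


@dataclass
class RunConfig:
    """File paths and study settings for one pipeline run."""

    registry: Path
    events: Path
    spells: Path
    deaths: Path
    imaging: Path
    codelist: Path
    exclusion_codelist: Path | None = None
    out_dir: Path = Path("ipflink_run")
    algorithms: tuple[str, ...] = tuple(ALGORITHM_PRESETS)
    gold_mode: DeathCauseMode = DeathCauseMode.ANYWHERE
    study: StudyConfig = field(default_factory=StudyConfig)

    def __post_init__(self) -> None:
        if not self.algorithms:
            raise ConfigurationError("at least one algorithm must be requested")
        unknown = [a for a in self.algorithms if a not in ALGORITHM_PRESETS]
        if unknown:
            raise ConfigurationError(f"unknown algorithm id(s): {unknown}")

    @classmethod
    def from_ini(cls, path: str | Path) -> "RunConfig":
        """Load a plain-text key = value config with [inputs]/[study]/[run]
        section headers."""
        parser = configparser.ConfigParser()
        read = parser.read(path)
        if not read:
            raise FileNotFoundError(path)
        inputs = parser["inputs"]
        study_sec = parser["study"] if parser.has_section("study") else {}
        run_sec = parser["run"] if parser.has_section("run") else {}
        study = StudyConfig(
            study_start=date.fromisoformat(
                study_sec.get("study_start", "2008-01-01")),
            study_end=date.fromisoformat(
                study_sec.get("study_end", "2018-12-31")),
            adult_age_years=int(study_sec.get("adult_age_years", 18)),
            death_grace_days=int(study_sec.get("death_grace_days", 60)),
        )
        algorithms = tuple(
            a.strip()
            for a in run_sec.get("algorithms", ",".join(ALGORITHM_PRESETS)).split(",")
            if a.strip())
        return cls(
            registry=Path(inputs["registry"]),
            events=Path(inputs["events"]),
            spells=Path(inputs["spells"]),
            deaths=Path(inputs["deaths"]),
            imaging=Path(inputs["imaging"]),
            codelist=Path(inputs["codelist"]),
            exclusion_codelist=(Path(inputs["exclusion_codelist"])
                                if inputs.get("exclusion_codelist") else None),
            out_dir=Path(run_sec.get("out_dir", "ipflink_run")),
            algorithms=algorithms,
            gold_mode=DeathCauseMode(run_sec.get("gold_mode", "anywhere")),
            study=study,
        )

    def hash(self) -> str:
        payload = json.dumps({
            "registry": str(self.registry), "events": str(self.events),
            "spells": str(self.spells), "deaths": str(self.deaths),
            "imaging": str(self.imaging), "codelist": str(self.codelist),
            "exclusion_codelist": str(self.exclusion_codelist),
            "algorithms": list(self.algorithms),
            "gold_mode": self.gold_mode.value,
            "study_start": self.study.study_start.isoformat(),
            "study_end": self.study.study_end.isoformat(),
            "adult_age_years": self.study.adult_age_years,
            "death_grace_days": self.study.death_grace_days,
        }, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class ReportBundle:
    """Everything a run produced, with the paths it was written to."""

    results: "object"  # ValidationResults
    manifest: dict
    out_dir: Path


def _stage(name: str, func, *args, **kwargs):
    try:
        return func(*args, **kwargs)
    except Exception as exc:
        raise type(exc)(f"[stage {name}] {exc}") from exc


def run_full_validation(config: RunConfig) -> ReportBundle:
    """Execute the whole pipeline and write the report bundle."""
    counts: dict[str, int] = {}

    registry = _stage("read registry", read_table, config.registry, "registry")
    events = _stage("read events", read_table, config.events, "events")
    spells = _stage("read spells", read_table, config.spells, "spells")
    deaths = _stage("read deaths", read_table, config.deaths, "deaths")
    imaging = _stage("read imaging", read_table, config.imaging, "imaging")
    codelist = _stage("read codelist", read_codelist, config.codelist)
    exclusions = (_stage("read exclusion codelist", read_codelist,
                         config.exclusion_codelist)
                  if config.exclusion_codelist else None)
    counts.update(registry_rows=len(registry), event_rows=len(events),
                  spell_rows=len(spells), death_rows=len(deaths),
                  imaging_rows=len(imaging))
    log.info("read %d registry rows, %d events, %d spells, %d deaths, "
             "%d imaging events", *counts.values())

    cohort = _stage("link", link_cohort, registry, events, spells, deaths,
                    imaging, codelist=codelist, exclusion_codelist=exclusions)
    eligible = [p for p in cohort
                if is_study_eligible(p.registry, p.earliest_broad, config.study)]
    counts["linked_patients"] = len(cohort)
    counts["eligible_patients"] = len(eligible)
    log.info("attrition: %d linked -> %d study-eligible",
             len(cohort), len(eligible))

    study = ValidationStudy(
        eligible,
        algorithms=[ALGORITHM_PRESETS[a] for a in config.algorithms],
        gold_mode=config.gold_mode,
        config=config.study,
    )
    results = _stage("validate", study.fit)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    results.frame().to_csv(out / "validation.csv", index=False)

    part = results.concordance
    pd.DataFrame([{**part.as_dict(), "total": part.total}]).to_csv(
        out / "concordance.csv", index=False)

    gs = results.gold_sensitivity
    pd.DataFrame([{
        "all_three_anywhere": gs.anywhere.all_three,
        "total_anywhere": gs.anywhere.total,
        "all_three_underlying": gs.underlying.all_three,
        "total_underlying": gs.underlying.total,
        "aurum_confirmed_pct": round_pct(gs.aurum_confirmed_share),
        "hes_confirmed_pct": round_pct(gs.hes_confirmed_share),
        "triple_share_pct": round_pct(gs.triple_share),
    }]).to_csv(out / "sensitivity_gold.csv", index=False)

    ps = results.position_sensitivity
    pd.DataFrame([{
        "n_primary_or_secondary": ps.n_primary_or_secondary,
        "n_top3": ps.n_top3,
        "ons_share_primary_or_secondary_pct": round_pct(
            ps.ons_share_primary_or_secondary),
        "ons_share_top3_pct": round_pct(ps.ons_share_top3),
    }]).to_csv(out / "sensitivity_positions.csv", index=False)

    trends = _stage("trends", code_usage_by_year, events, codelist,
                    (config.study.study_start.year, config.study.study_end.year))
    trends.frame.to_csv(out / "trends.csv", index=False)

    for source in ("aurum", "hes"):
        causes = noncordant_death_causes(eligible, source, config.study)
        pd.DataFrame(causes, columns=["underlying_icd10", "count"]).to_csv(
            out / f"death_causes_{source}.csv", index=False)

    manifest = {
        "config_hash": config.hash(),
        "row_counts": counts,
        "algorithms": list(config.algorithms),
        "gold_mode": config.gold_mode.value,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    (out / "summary.txt").write_text(results.summary() + "\n")
    return ReportBundle(results=results, manifest=manifest, out_dir=out)
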