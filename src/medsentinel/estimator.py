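"""National prevalence estimation from sentinel surveillance.

The market is partitioned into surveyed sentinel strata and residual
(nonsentinel) subsectors. Each surveyed stratum contributes its measured
prevalence; each residual stratum contributes a documented assumption (with
a source note and a low/high band — the assumption ledger). The national
estimate is the volume-weighted mixture

    prevalence = ( sum_g p_hat_g V_g + sum_r p_assumed_r V_r ) / sum V

i.e. the estimated count of poor-quality units over the total market volume.
Sensitivity bounds substitute every surveyed stratum's confidence limits and
every ledger low/high simultaneously, bracketing the estimate under the most
pessimistic and optimistic defensible inputs. The whole model exports to two
plain CSV files that are sufficient to reproduce the estimate exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .sentinel import MembershipPartition, PrevalenceEstimate
from .types import MarketSnapshot, ValidationError

__all__ = [
    "Assumption",
    "VolumeTable",
    "NationalEstimate",
    "stratum_volumes",
    "apply_assumptions",
    "national_prevalence",
    "sensitivity_bounds",
    "export_model",
    "load_model",
]


@dataclass(frozen=True)
class Assumption:
    """One documented residual-stratum prevalence assumption."""

    assumption_id: str
    stratum_id: str
    assumed_prevalence: float
    low: float
    high: float
    source_note: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.low <= self.assumed_prevalence <= self.high <= 1.0):
            raise ValidationError(
                f"assumption {self.assumption_id}: need 0 <= low <= assumed <= high <= 1"
            )
        if not self.source_note or not self.source_note.strip():
            raise ValidationError(
                f"assumption {self.assumption_id}: source_note is mandatory — "
                "every assumption must be documented"
            )


@dataclass
class VolumeTable:
    """Annual unit volumes per stratum; conserves the market total exactly."""

    volumes: dict[str, int]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.volumes.values()):
            raise ValidationError("stratum volumes must be >= 0")

    @property
    def total_volume(self) -> int:
        return sum(self.volumes.values())


@dataclass
class NationalEstimate:
    stream: str
    sentinel_count: float
    residual_count: float
    denominator: int
    sensitivity_low: float
    sensitivity_high: float
    stratum_prevalence: dict[str, float]
    stratum_source: dict[str, str]  # stratum -> "surveyed" | "assumed"
    ledger: list[Assumption]

    @property
    def numerator(self) -> float:
        return self.sentinel_count + self.residual_count

    @property
    def prevalence(self) -> float:
        return self.numerator / self.denominator

    def validate(self) -> None:
        ps = [p for s, p in self.stratum_prevalence.items() if self.volume_of(s) > 0]
        if ps and not (min(ps) - 1e-12 <= self.prevalence <= max(ps) + 1e-12):
            raise ValidationError("national prevalence outside stratum range")
        if not (self.sensitivity_low - 1e-12 <= self.prevalence <= self.sensitivity_high + 1e-12):
            raise ValidationError("prevalence outside sensitivity bounds")

    _volumes: dict[str, int] | None = None

    def volume_of(self, stratum: str) -> int:
        return (self._volumes or {}).get(stratum, 0)


def stratum_volumes(
    market: MarketSnapshot,
    partition: MembershipPartition,
    residual_key: str = "sector",
) -> VolumeTable:
    """Stock volumes per stratum.

    Sentinel strata sum stock over their assigned products; residual volume is
    split into subsectors by ``residual_key`` (default: outlet sector, giving
    strata like ``residual:public``).
    """
    volumes: dict[str, int] = {}
    for (pid, oid), units in market.stock.items():
        if units <= 0:
            continue
        group = partition.assigned_group.get(pid, "residual")
        if group == "residual":
            if residual_key == "sector":
                stratum = f"residual:{market.outlets[oid].sector}"
            else:
                stratum = "residual"
        else:
            stratum = group
        volumes[stratum] = volumes.get(stratum, 0) + units
    return VolumeTable(volumes=volumes)


def apply_assumptions(
    ledger: Sequence[Assumption], residual_strata: Sequence[str]
) -> dict[str, float]:
    """Validate the ledger against the residual strata and return the assumed
    prevalences. Refuses incomplete or duplicated ledgers."""
    by_stratum: dict[str, Assumption] = {}
    for a in ledger:
        if a.stratum_id in by_stratum:
            raise ValidationError(f"duplicate assumption for stratum {a.stratum_id}")
        by_stratum[a.stratum_id] = a
    missing = [s for s in residual_strata if s not in by_stratum]
    if missing:
        raise ValidationError(
            f"assumption ledger incomplete: no assumption for strata {missing}"
        )
    return {s: by_stratum[s].assumed_prevalence for s in residual_strata}


def _split_strata(
    volumes: VolumeTable,
    group_estimates: Mapping[str, PrevalenceEstimate],
) -> tuple[list[str], list[str]]:
    surveyed = [s for s in volumes.volumes if s in group_estimates]
    residual = [s for s in volumes.volumes if s not in group_estimates]
    return surveyed, residual


def national_prevalence(
    stream: str,
    group_estimates: Mapping[str, PrevalenceEstimate],
    volumes: VolumeTable,
    ledger: Sequence[Assumption],
) -> NationalEstimate:
    """Combine surveyed prevalences, volumes, and the assumption ledger into
    the national volume-weighted prevalence with sensitivity bounds."""
    if volumes.total_volume <= 0:
        raise ValidationError("total volume must be > 0")
    surveyed, residual = _split_strata(volumes, group_estimates)
    assumed = apply_assumptions(ledger, residual)

    sentinel_count = sum(
        group_estimates[s].point * volumes.volumes[s] for s in surveyed
    )
    residual_count = sum(assumed[s] * volumes.volumes[s] for s in residual)

    low, high = sensitivity_bounds(group_estimates, ledger, volumes)

    stratum_prev = {s: group_estimates[s].point for s in surveyed}
    stratum_prev.update({s: assumed[s] for s in residual})
    est = NationalEstimate(
        stream=stream,
        sentinel_count=sentinel_count,
        residual_count=residual_count,
        denominator=volumes.total_volume,
        sensitivity_low=low,
        sensitivity_high=high,
        stratum_prevalence=stratum_prev,
        stratum_source={
            **{s: "surveyed" for s in surveyed},
            **{s: "assumed" for s in residual},
        },
        ledger=list(ledger),
    )
    est._volumes = dict(volumes.volumes)
    est.validate()
    return est


def sensitivity_bounds(
    group_estimates: Mapping[str, PrevalenceEstimate],
    ledger: Sequence[Assumption],
    volumes: VolumeTable,
) -> tuple[float, float]:
    """Pessimistic/optimistic envelope: lower bound uses every surveyed
    stratum's CI lower limit and every ledger low; upper bound the CI upper
    limits and ledger highs."""
    surveyed, residual = _split_strata(volumes, group_estimates)
    ledger_by_stratum = {a.stratum_id: a for a in ledger}
    missing = [s for s in residual if s not in ledger_by_stratum]
    if missing:
        raise ValidationError(f"no ledger assumption for strata {missing}")
    total = volumes.total_volume
    lo = (
        sum(group_estimates[s].ci_low * volumes.volumes[s] for s in surveyed)
        + sum(ledger_by_stratum[s].low * volumes.volumes[s] for s in residual)
    ) / total
    hi = (
        sum(group_estimates[s].ci_high * volumes.volumes[s] for s in surveyed)
        + sum(ledger_by_stratum[s].high * volumes.volumes[s] for s in residual)
    ) / total
    return float(lo), float(hi)


def export_model(
    estimate: NationalEstimate,
    volumes: VolumeTable,
    group_estimates: Mapping[str, PrevalenceEstimate],
    path: str | Path,
) -> None:
    """Write the spreadsheet model: ``strata.csv`` (one row per stratum with
    volume, prevalence, CI/band limits, source, and note) and ``estimate.csv``
    (numerator, denominator, prevalence, bounds). The two files are sufficient
    to reproduce the estimate exactly."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    ledger_by_stratum = {a.stratum_id: a for a in estimate.ledger}
    rows = []
    for stratum, vol in sorted(volumes.volumes.items()):
        source = estimate.stratum_source[stratum]
        if source == "surveyed":
            ge = group_estimates[stratum]
            rows.append(
                {
                    "stratum_id": stratum,
                    "volume": vol,
                    "prevalence": ge.point,
                    "low": ge.ci_low,
                    "high": ge.ci_high,
                    "k": ge.k,
                    "n": ge.n,
                    "source": "surveyed",
                    "note": f"sentinel survey, {ge.ci_method} 95% CI",
                }
            )
        else:
            a = ledger_by_stratum[stratum]
            rows.append(
                {
                    "stratum_id": stratum,
                    "volume": vol,
                    "prevalence": a.assumed_prevalence,
                    "low": a.low,
                    "high": a.high,
                    "k": None,
                    "n": None,
                    "source": "assumed",
                    "note": a.source_note,
                }
            )
    pd.DataFrame(rows).to_csv(path / "strata.csv", index=False)
    pd.DataFrame(
        [
            {
                "stream": estimate.stream,
                "numerator": estimate.numerator,
                "denominator": estimate.denominator,
                "prevalence": estimate.prevalence,
                "sensitivity_low": estimate.sensitivity_low,
                "sensitivity_high": estimate.sensitivity_high,
            }
        ]
    ).to_csv(path / "estimate.csv", index=False)


def load_model(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read back an exported model (strata and estimate tables)."""
    path = Path(path)
    return pd.read_csv(path / "strata.csv"), pd.read_csv(path / "estimate.csv")


def recompute_from_model(strata: pd.DataFrame) -> tuple[float, float, float]:
    """Recompute (prevalence, low, high) from an exported strata table alone —
    the transparency check: the spreadsheet is self-contained."""
    total = strata["volume"].sum()
    prev = float((strata["prevalence"] * strata["volume"]).sum() / total)
    lo = float((strata["low"] * strata["volume"]).sum() / total)
    hi = float((strata["high"] * strata["volume"]).sum() / total)
    return prev, lo, hi
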