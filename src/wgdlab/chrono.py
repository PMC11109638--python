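"""Rate calibration from dated ortholog divergences, and WGD dating.

Under a molecular clock the expected synonymous divergence of two lineages
separated T years ago is Ks = 2·r·T, so a dated speciation with an observed
ortholog Ks peak yields a rate estimate r = Ks/(2T), and a paralog Ks peak
dates its duplication event at T = Ks/(2r). Ages are kept in years
internally; MYA appears only at the I/O boundary.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

YEARS_PER_MY = 1e6
RATE_HETEROGENEITY_WARN = 0.25  # warn when per-point rates spread by >25%


@dataclass
class CalibrationPoint:
    species_pair: tuple[str, str]
    divergence_time: float  # years
    ortholog_ks_peak: float
    peak_ci: tuple[float, float] | None = None

    @classmethod
    def from_mya(cls, species_pair, divergence_mya, ortholog_ks_peak, peak_ci=None):
        return cls(
            species_pair=tuple(species_pair),
            divergence_time=divergence_mya * YEARS_PER_MY,
            ortholog_ks_peak=ortholog_ks_peak,
            peak_ci=peak_ci,
        )


@dataclass
class RateEstimate:
    rate: float  # synonymous substitutions / site / year
    per_point_rates: list[float]
    method: str = "mean"


@dataclass
class WgdEvent:
    label: str
    ks_peak: float
    age: float  # years
    age_ci: tuple[float, float] | None = None
    rate: float | None = None

    @property
    def age_mya(self) -> float:
        return round(self.age / YEARS_PER_MY, 2)

    @property
    def age_ci_mya(self) -> tuple[float, float] | None:
        if self.age_ci is None:
            return None
        return (round(self.age_ci[0] / YEARS_PER_MY, 2), round(self.age_ci[1] / YEARS_PER_MY, 2))


def calibrate_rate(points: list[CalibrationPoint], method: str = "mean") -> RateEstimate:
    """Pooled synonymous substitution rate from dated ortholog Ks peaks.

    Per point r_i = Ks_i / (2·T_i); the pooled estimate is their arithmetic
    mean (or median). A warning is raised when the per-point rates spread by
    more than 25% of their mean — a sign of lineage rate heterogeneity that
    a single pooled rate cannot capture.
    """
    if not points:
        raise ValueError("at least one calibration point is required")
    if method not in ("mean", "median"):
        raise ValueError(f"unknown aggregation method {method!r}")
    rates = []
    for p in points:
        if p.divergence_time <= 0 or p.ortholog_ks_peak <= 0:
            raise ValueError(
                f"calibration point {p.species_pair}: time and Ks peak must be positive"
            )
        rates.append(p.ortholog_ks_peak / (2.0 * p.divergence_time))
    if method == "mean":
        pooled = sum(rates) / len(rates)
    else:
        s = sorted(rates)
        mid = len(s) // 2
        pooled = s[mid] if len(s) % 2 else 0.5 * (s[mid - 1] + s[mid])
    if len(rates) > 1 and (max(rates) - min(rates)) / pooled > RATE_HETEROGENEITY_WARN:
        warnings.warn(
            "per-point synonymous rates differ by more than 25%: "
            "lineage rate heterogeneity; the pooled rate may be biased",
            stacklevel=2,
        )
    return RateEstimate(rate=pooled, per_point_rates=rates, method=method)


def estimate_wgd_age(
    ks_peak: float,
    rate: float,
    peak_ci: tuple[float, float] | None = None,
    label: str = "",
) -> WgdEvent:
    """Date a duplication event: age = Ks_peak / (2·r), CI scaled identically."""
    if ks_peak <= 0 or rate <= 0:
        raise ValueError("ks_peak and rate must be positive")
    age = ks_peak / (2.0 * rate)
    ci = None
    if peak_ci is not None:
        ci = (peak_ci[0] / (2.0 * rate), peak_ci[1] / (2.0 * rate))
    return WgdEvent(label=label, ks_peak=ks_peak, age=age, age_ci=ci, rate=rate)


# ---------------------------------------------------------------------------
# I/O


def read_calibration_tsv(path) -> list[CalibrationPoint]:
    """TSV columns: species_a, species_b, divergence_mya, ortholog_ks_peak."""
    points = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("species_a\t") or not line.strip():
                continue
            a, b, t_mya, ks = line.rstrip("\n").split("\t")[:4]
            points.append(CalibrationPoint.from_mya((a, b), float(t_mya), float(ks)))
    return points


def write_wgd_report(events: list[WgdEvent], path_json, path_tsv=None, meta: dict | None = None) -> None:
    payload = {
        "events": [
            {
                "label": e.label,
                "ks_peak": e.ks_peak,
                "rate_used": e.rate,
                "age_mya": e.age_mya,
                "ci_low_mya": None if e.age_ci_mya is None else e.age_ci_mya[0],
                "ci_high_mya": None if e.age_ci_mya is None else e.age_ci_mya[1],
            }
            for e in events
        ]
    }
    if meta:
        payload["_meta"] = meta
    with open(path_json, "w") as fh:
        json.dump(payload, fh, indent=1)
    if path_tsv is not None:
        with open(path_tsv, "w") as fh:
            for key, val in (meta or {}).items():
                fh.write(f"# {key}: {val}\n")
            fh.write("label\tks_peak\trate_used\tage_mya\tci_low\tci_high\n")
            for e in payload["events"]:
                fh.write(
                    f"{e['label']}\t{e['ks_peak']}\t{e['rate_used']}\t{e['age_mya']}\t"
                    f"{e['ci_low_mya']}\t{e['ci_high_mya']}\n"
                )
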