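"""Synthetic-data generators for every pipeline input.

The generators emulate the statistical structure of a temperate coastal
monthly virome time series: a 32-month span sampled 27 times (five interior
months missing), seasonal vOTUs as phase-grouped annual sinusoids on a
log-normal abundance scale, non-seasonal vOTUs as random walks or single
spikes, an environment table with an annual temperature cycle and nutrients
in anti-phase, per-sample VCFs whose site sets turn over month by month with
an optional annual-recurrence pool, and chronotype gene annotations with
planted seasonal enrichment.  Every generator is a pure function of
(config, seed), and ground-truth labels are always returned or written next
to the data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core_data import AbundanceMatrix, EnvMatrix

__all__ = [
    "SimConfig",
    "simulate_abundance",
    "simulate_env",
    "simulate_variant_sets",
    "simulate_variants",
    "simulate_annotations",
    "month_grid_dates",
]

_START_YEAR, _START_MONTH = 2018, 11  # study calendar: Nov 2018 onward


@dataclass
class SimConfig:
    """Generator settings.  Defaults are the study conditions: a 32-month
    monthly grid with 27 retained samples, annual sinusoids of amplitude 3
    with noise sd 0.3 grouped into 6 phase groups, a 20% non-seasonal
    fraction, monthly site turnover 0.2 and, where planted, annual-recurrence
    weight 0.5 and 3 of 100 categories enriched at ratio effect +0.4."""

    n_votus: int = 150
    n_months: int = 32
    n_dropped_months: int = 5
    n_chronotypes: int = 6
    phase_offsets_months: tuple | None = None   # default: evenly spaced over 12
    amplitude: float = 3.0
    noise_sd: float = 0.3
    fraction_nonseasonal: float = 0.2
    spike_prob: float = 0.5                     # spike vs random-walk non-seasonal
    env_noise_sd: float = 0.05
    n_sites: int = 100
    turnover: float = 0.2
    recurrence_weight: float = 0.0
    annual_pool_factor: float = 2.0             # pool size / monthly recurrent draw
    contig_length: int = 20000
    fail_fraction: float = 0.1                  # decoy records failing VCF filters
    n_categories: int = 100
    n_enriched: int = 3
    enrichment_effect: float = 0.4              # ratio units per member
    background_rate: float = 0.2                # Poisson gene rate per member
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_nonseasonal", "spike_prob", "turnover",
                     "recurrence_weight", "fail_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.phase_offsets_months is None:
            self.phase_offsets_months = tuple(
                12.0 * g / self.n_chronotypes for g in range(self.n_chronotypes))


def month_grid_dates(n_months: int) -> list[str]:
    """ISO mid-month dates for the study grid starting Nov 2018."""
    base = _START_YEAR * 12 + (_START_MONTH - 1)
    out = []
    for t in range(n_months):
        y, m = divmod(base + t, 12)
        out.append(f"{y:04d}-{m + 1:02d}-15")
    return out


def sampled_months(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Grid months retained after dropping interior months (first and last
    are always sampled, so alignment never needs to extrapolate)."""
    interior = np.arange(1, cfg.n_months - 1)
    dropped = rng.choice(interior, size=cfg.n_dropped_months, replace=False)
    return np.setdiff1d(np.arange(cfg.n_months), dropped)


# ---------------------------------------------------------------------------
# abundance
# ---------------------------------------------------------------------------

def simulate_abundance(cfg: SimConfig) -> tuple[AbundanceMatrix, pd.DataFrame]:
    """Abundance table at the retained sample dates plus ground truth.

    Seasonal series: exp(scale) * max(0, 1 + amplitude * sin(2 pi (t +
    phase_g) / 12)) + truncated Gaussian noise, with phase group g the
    planted chronotype.  Non-seasonal series: a reflected random walk or a
    single-spike profile.  Truth columns: votu_id, seasonal, group (phase
    group id or -1), phase_months.
    """
    rng = np.random.default_rng(cfg.seed)
    months = sampled_months(cfg, rng)
    t = months[None, :].astype(float)
    n_non = int(round(cfg.n_votus * cfg.fraction_nonseasonal))
    n_sea = cfg.n_votus - n_non
    ids = [f"vOTU_{i:05d}" for i in range(cfg.n_votus)]
    groups = np.full(cfg.n_votus, -1)
    groups[:n_sea] = rng.integers(cfg.n_chronotypes, size=n_sea)
    phases = np.array(cfg.phase_offsets_months)
    values = np.empty((cfg.n_votus, months.size))
    scale = np.exp(rng.normal(0.0, 1.0, size=cfg.n_votus))
    for i in range(cfg.n_votus):
        if groups[i] >= 0:
            base = np.clip(1.0 + cfg.amplitude
                           * np.sin(2 * np.pi * (t[0] + phases[groups[i]]) / 12.0),
                           0.0, None)
            series = scale[i] * base + rng.normal(0.0, cfg.noise_sd, months.size)
        elif rng.random() < cfg.spike_prob:
            series = np.full(months.size, 0.05 * scale[i])
            series[rng.integers(months.size)] += scale[i] * (2.0 + rng.random())
            series += rng.normal(0.0, cfg.noise_sd * 0.1, months.size)
        else:
            series = scale[i] * np.abs(
                np.cumsum(rng.normal(0.0, 1.0, months.size))) / np.sqrt(months.size)
            series += rng.normal(0.0, cfg.noise_sd * 0.1, months.size)
        values[i] = np.clip(series, 0.0, None)
    dates = month_grid_dates(cfg.n_months)
    sample_dates = [dates[m] for m in months]
    am = AbundanceMatrix(ids, sample_dates, months - months.min(), values)
    truth = pd.DataFrame({"votu_id": ids, "seasonal": groups >= 0,
                          "group": groups,
                          "phase_months": [phases[g] if g >= 0 else float("nan")
                                           for g in groups]})
    return am, truth


# ---------------------------------------------------------------------------
# environment
# ---------------------------------------------------------------------------

_ENV_ARCHETYPES = {
    # name: (annual amplitude sign/strength, phase months, mean, sd of cycle)
    "temperature": (1.0, 0.0, 12.0, 4.0),     # peaks in August
    "salinity": (0.4, 1.0, 35.0, 0.3),
    "O2": (-0.5, 0.5, 260.0, 20.0),
    "NO2_NO3": (-1.0, 0.0, 5.0, 4.0),         # anti-phase with temperature
    "PO4": (-1.0, 0.5, 0.4, 0.3),
    "SiO2": (-1.0, -0.5, 4.0, 3.0),
    "NH4": (-0.6, 2.0, 0.5, 0.3),
    "chlorophyll_a": (0.5, -2.0, 1.5, 1.0),
    "PAR": (1.0, -1.0, 30.0, 20.0),
}


def simulate_env(cfg: SimConfig) -> EnvMatrix:
    """Nine-parameter environment table on the same sample dates: temperature
    as an annual sinusoid peaking in summer, the dissolved nutrients (NO2+NO3,
    PO4, SiO2, NH4) in anti-phase, salinity/oxygen with weaker cycles, plus
    Gaussian noise scaled to each parameter's cycle."""
    rng = np.random.default_rng(cfg.seed)
    months = sampled_months(cfg, rng)
    month_of_year = (_START_MONTH - 1 + months) % 12   # 0 = January
    raw = []
    names = list(_ENV_ARCHETYPES)
    for name in names:
        strength, phase, mean, sd = _ENV_ARCHETYPES[name]
        # peak in August (month index 7) for positive-strength parameters
        cyc = strength * np.cos(2 * np.pi * (month_of_year - 7 - phase) / 12.0)
        raw.append(mean + sd * cyc
                   + sd * cfg.env_noise_sd * rng.normal(size=months.size) / max(abs(strength), 0.3))
    dates = month_grid_dates(cfg.n_months)
    return EnvMatrix(names, [dates[m] for m in months], months - months.min(),
                     np.array(raw))


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

def simulate_variant_sets(cfg: SimConfig, contig_ids,
                          months=None) -> dict[str, dict[int, set]]:
    """Evolving per-month site sets per contig.

    Each month a fraction ``turnover`` of the current sites is replaced;
    replacements are drawn from a month-of-year annual pool with probability
    ``recurrence_weight`` (the recurrence mechanism) and are otherwise brand
    new.  Site = (1-based position, alternate allele).
    """
    rng = np.random.default_rng(cfg.seed + 1)
    if months is None:
        months = list(range(cfg.n_months))
    alleles = "ACGT"
    out: dict[str, dict[int, set]] = {}
    n_replace = int(round(cfg.turnover * cfg.n_sites))
    n_recur = int(round(cfg.recurrence_weight * n_replace))
    pool_size = max(1, int(round(cfg.annual_pool_factor * max(n_recur, 1))))
    for cid in map(str, contig_ids):
        next_pos = 1
        def new_sites(n):
            # alt drawn from the three non-reference bases (ref is keyed to
            # the position, matching the VCF writer)
            nonlocal next_pos
            sites = []
            for i in range(n):
                pos = next_pos + i
                ref = alleles[(pos - 1) % 4]
                options = alleles.replace(ref, "")
                sites.append((pos, options[rng.integers(3)]))
            next_pos += n
            return sites
        pools = [new_sites(pool_size) for _ in range(12)] \
            if cfg.recurrence_weight > 0 else None
        current = set(new_sites(cfg.n_sites))
        series: dict[int, set] = {}
        prev = None
        for m in range(max(months) + 1):
            if prev is not None:
                lost = rng.choice(len(current), size=min(n_replace, len(current)),
                                  replace=False)
                cur_list = sorted(current)
                for i in lost:
                    current.discard(cur_list[i])
                gains = []
                if pools is not None and n_recur:
                    moy = (_START_MONTH - 1 + m) % 12
                    pick = rng.choice(pool_size, size=min(n_recur, pool_size),
                                      replace=False)
                    gains.extend(pools[moy][i] for i in pick)
                gains.extend(new_sites(n_replace - len(gains)))
                current.update(gains)
            prev = m
            if m in months:
                series[m] = set(current)
        out[cid] = series
    return out


def simulate_variants(cfg: SimConfig, contig_ids, out_dir=None,
                      months=None) -> tuple[dict, pd.DataFrame]:
    """Site sets plus a coverage table; optionally also written as per-sample
    VCF 4.2 files (one per month) and coverage.tsv under ``out_dir``.

    A ``fail_fraction`` of extra decoy records per contig per sample is
    emitted with QUAL < 20, DP < 10 or allele frequency <= 1% so the filter
    path is exercised; decoys are positions beyond the true site range.
    """
    sets = simulate_variant_sets(cfg, contig_ids, months=months)
    rng = np.random.default_rng(cfg.seed + 2)
    all_months = sorted({m for s in sets.values() for m in s})
    cov_rows = []
    dates = month_grid_dates(max(all_months) + 1)
    for cid in map(str, contig_ids):
        for m in all_months:
            depth = float(rng.uniform(15, 60))
            cov_rows.append((cid, m, dates[m], depth, float(rng.uniform(0.92, 1.0))))
    coverage = pd.DataFrame(cov_rows, columns=["votu_id", "month", "sample_date",
                                               "mean_depth", "breadth10"])
    if out_dir is not None:
        out = Path(out_dir)
        (out / "vcfs").mkdir(parents=True, exist_ok=True)
        depth_lookup = {(r.votu_id, r.month): r.mean_depth
                        for r in coverage.itertuples(index=False)}
        for m in all_months:
            _write_vcf(out / "vcfs" / f"{dates[m]}.vcf", sets, m, cfg, rng,
                       depth_lookup)
        coverage.to_csv(out / "coverage.tsv", sep="\t", index=False,
                        float_format="%.10g")
    return sets, coverage


def _write_vcf(path, sets, month, cfg, rng, depth_lookup) -> None:
    lines = ["##fileformat=VCFv4.2",
             '##INFO=<ID=DP,Number=1,Type=Integer,Description="Raw read depth">',
             '##INFO=<ID=AF,Number=A,Type=Float,Description="Alternate allele frequency">']
    for cid in sorted(sets):
        lines.append(f"##contig=<ID={cid},length={cfg.contig_length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    refs = "ACGT"
    for cid in sorted(sets):
        depth = depth_lookup.get((cid, month), 30.0)
        records = []
        for pos, alt in sorted(sets[cid].get(month, set())):
            qual = 20.0 + float(rng.uniform(0, 200))
            dp = max(10, int(rng.poisson(depth)))
            af = float(rng.uniform(0.02, 1.0))
            records.append((pos, alt, qual, dp, af))
        n_fail = int(round(cfg.fail_fraction * len(records)))
        base = cfg.n_sites * 200  # decoys live beyond any true position
        for i in range(n_fail):
            kind = rng.integers(3)
            qual = float(rng.uniform(0, 19.9)) if kind == 0 else 20.0 + float(rng.uniform(0, 50))
            dp = int(rng.integers(1, 10)) if kind == 1 else max(10, int(rng.poisson(depth)))
            af = float(rng.uniform(0.0001, 0.01)) if kind == 2 else float(rng.uniform(0.02, 1.0))
            records.append((base + month * cfg.n_sites + i + 1,
                            refs[rng.integers(4)], qual, dp, af))
        for pos, alt, qual, dp, af in sorted(records):
            ref = refs[(pos - 1) % 4]
            alt = alt if alt != ref else refs[(pos) % 4]
            lines.append(f"{cid}\t{pos}\t.\t{ref}\t{alt}\t{qual:.1f}\t.\t"
                         f"DP={dp};AF={af:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def simulate_annotations(cfg: SimConfig, memberships: dict[str, int],
                         seasonal_chronotypes: set[int]) -> tuple[pd.DataFrame, list[str]]:
    """Per-vOTU functional-category counts with planted seasonal enrichment.

    Background counts per (vOTU, category) are Poisson(background_rate); the
    first ``n_enriched`` categories get an extra Poisson(enrichment_effect)
    per member of a seasonal chronotype, raising the expected chronotype
    ratio by the configured effect.  Returns (long table with count > 0 rows,
    list of enriched category ids).
    """
    rng = np.random.default_rng(cfg.seed + 3)
    cats = [f"phrog_{i:04d}" for i in range(cfg.n_categories)]
    enriched = cats[:cfg.n_enriched]
    rows = []
    for votu in sorted(memberships):
        seasonal = memberships[votu] in seasonal_chronotypes
        counts = rng.poisson(cfg.background_rate, size=cfg.n_categories)
        if seasonal and cfg.n_enriched:
            counts[:cfg.n_enriched] += rng.poisson(cfg.enrichment_effect,
                                                   size=cfg.n_enriched)
        for cat, n in zip(cats, counts):
            if n > 0:
                rows.append((votu, cat, int(n)))
    return (pd.DataFrame(rows, columns=["votu_id", "category_id", "count"]),
            enriched)
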