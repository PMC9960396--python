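"""Synthetic monthly phage/host community generator.

Emulates the statistical structure of a multi-year, monthly, two-size-fraction
marine T4-like cyanophage survey: a long-tailed (lognormal) rank-abundance
distribution dominated by low-abundance species, four per-species dynamic
archetypes (seasonal, persistent, occasional, sporadic), two correlated
size-fraction observations (free virions vs. cells) of the same latent
community, picocyanobacterial host taxa seasonally coupled to groups of
seasonal phages, environmental covariates, and months missing completely at
random.

Every quantity is generated from a single integer seed through a
``numpy.random.SeedSequence`` spawning scheme, so individual species'
trajectories are reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ARCHETYPES = ("seasonal", "persistent", "occasional", "sporadic")

#: sub-stream indices for SeedSequence spawning (kept stable across versions)
_STREAM_TRAJ = 0
_STREAM_MISSING = 1
_STREAM_COUNTS = 2
_STREAM_HOSTS = 3
_STREAM_ENV = 4
_STREAM_GENES = 5
_STREAM_FASTA = 6
_STREAM_BASELINES = 7


class UnknownArchetypeError(ValueError):
    """Raised when an archetype name is not one of the four dynamic classes."""


@dataclass(frozen=True)
class ArchetypeSpec:
    """Generative parameters for one species' dynamic archetype.

    ``baseline_log_abundance`` and ``seasonal_amplitude`` are in natural-log
    units of latent (unnormalised) abundance; ``noise_sd`` is the SD of the
    lognormal month-to-month noise on the same scale, so amplitude-to-noise
    ratios are directly comparable.  ``season_width`` is the width in months
    of the raised-cosine seasonal window outside of which a seasonal species
    is absent (virions decayed below detectability).
    """

    archetype: str
    peak_month: int = 7
    baseline_log_abundance: float = 0.0
    seasonal_amplitude: float = 0.0
    occurrence_prob: float = 1.0
    noise_sd: float = 0.5
    season_width: float = 8.0

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise UnknownArchetypeError(
                f"unknown archetype {self.archetype!r}; expected one of {ARCHETYPES}"
            )
        if self.archetype != "seasonal" and self.seasonal_amplitude != 0:
            raise ValueError("seasonal_amplitude must be 0 for non-seasonal archetypes")
        if not (0.0 <= self.occurrence_prob <= 1.0):
            raise ValueError("occurrence_prob must be in [0, 1]")
        if self.noise_sd < 0 or self.seasonal_amplitude < 0:
            raise ValueError("noise_sd and seasonal_amplitude must be >= 0")
        if self.archetype == "seasonal" and not (1 <= self.peak_month <= 12):
            raise ValueError("peak_month must be in 1..12")


def seasonal_bump(month_of_year: np.ndarray, peak_month: int, width: float) -> np.ndarray:
    """Raised-cosine seasonal window on the 12-month circle.

    Equals 1 at ``peak_month``, falls as ``0.5*(1+cos(2*pi*d/width))`` with
    circular month distance ``d``, and is exactly 0 for ``|d| >= width/2``.
    """
    d = (np.asarray(month_of_year, dtype=float) - peak_month + 6.0) % 12.0 - 6.0
    b = 0.5 * (1.0 + np.cos(2.0 * np.pi * d / width))
    b[np.abs(d) >= width / 2.0] = 0.0
    return b


def simulate_trajectory(
    spec: ArchetypeSpec, months: pd.PeriodIndex, seed: int | np.random.SeedSequence
) -> np.ndarray:
    """Latent (unnormalised) monthly abundance series for one species.

    seasonal    -- 12-month-periodic raised-cosine bump centred on
                   ``peak_month``; log-abundance inside the window is
                   ``baseline + amplitude * bump + N(0, noise_sd)``, zero
                   outside it.
    persistent  -- lognormal around the baseline, nonzero every month.
    occasional / sporadic -- present in a Bernoulli(occurrence_prob) subset
                   of months, lognormal around the baseline when present.

    Identical ``spec``, ``months`` and ``seed`` reproduce the series exactly.
    """
    if len(months) == 0:
        raise ValueError("months must be nonempty")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    n = len(months)
    moy = np.asarray([m.month for m in months], dtype=float)
    noise = rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd > 0 else np.zeros(n)
    base = spec.baseline_log_abundance

    if spec.archetype == "seasonal":
        bump = seasonal_bump(moy, spec.peak_month, spec.season_width)
        latent = np.where(bump > 0, np.exp(base + spec.seasonal_amplitude * bump + noise), 0.0)
    elif spec.archetype == "persistent":
        latent = np.exp(base + noise)
    else:  # occasional, sporadic
        present = rng.random(n) < spec.occurrence_prob
        latent = np.where(present, np.exp(base + noise), 0.0)
    return latent


@dataclass
class SpeciesCountTable:
    """Species x sample read-count matrix with mapping metadata.

    ``counts`` columns are sample labels (calendar months as 'YYYY-MM');
    ``gene_length`` (bp) and ``library_size`` (total reads) index species and
    samples respectively.  ``base_coverage`` is the fraction of marker bases
    covered by at least one read, ``mean_depth`` the mean fold coverage.
    """

    counts: pd.DataFrame
    gene_length: pd.Series
    library_size: pd.Series
    base_coverage: pd.DataFrame
    mean_depth: pd.DataFrame
    fraction_label: str

    def __post_init__(self) -> None:
        if (self.gene_length <= 0).any():
            raise ValueError("gene_length must be > 0")
        if (self.library_size <= 0).any():
            raise ValueError("library_size must be > 0")

    @property
    def species(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns


@dataclass
class SyntheticDataset:
    counts_viral: SpeciesCountTable
    counts_cellular: SpeciesCountTable
    host_abundance: pd.DataFrame  # taxon x sampled month, absolute cells/mL
    env: pd.DataFrame  # covariate x sampled month
    truth: pd.DataFrame  # species, archetype, peak_month, linked_host
    months: pd.PeriodIndex  # full monthly axis including missing months
    missing: pd.Series  # bool per month of the full axis
    sequences: dict[str, str]  # species -> synthetic marker gene sequence
    seed: int

    @property
    def sampled_months(self) -> pd.PeriodIndex:
        return self.months[~self.missing.to_numpy()]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the default synthetic community.

    Defaults mirror the emulated survey design: 60 monthly samples, four
    archetypes with 50 species each, a viral-fraction library ~5x the mapped
    depth of the cellular fraction, ~10% of months missing, and hosts
    strongly coupled to seasonal phage groups.
    """

    n_seasonal: int = 50
    n_persistent: int = 50
    n_occasional: int = 50
    n_sporadic: int = 50
    n_months: int = 60
    start_month: str = "2009-05"
    library_size_viral: int = 100_000
    library_size_cellular: int = 20_000
    missing_prob: float = 0.1
    host_coupling_strength: float = 0.8
    n_coupled_hosts: int = 8
    n_uncoupled_hosts: int = 4
    host_lag_months: int = 0
    fraction_noise_sd: float = 0.3
    read_length: int = 100
    gene_length_range: tuple[int, int] = (600, 900)
    seasonal_amplitude: float = 1.5
    noise_sd: float = 0.5
    season_width: float = 8.0
    baseline_seasonal: float = 0.5
    baseline_persistent: float = 0.0
    baseline_occasional: float = -0.5
    baseline_sporadic: float = -0.5
    occurrence_occasional: float = 0.4
    occurrence_sporadic: float = 0.08
    species_log_sd: float = 1.0  # lognormal spread of per-species baselines
    marker_length: int = 750

    @property
    def n_species(self) -> int:
        return self.n_seasonal + self.n_persistent + self.n_occasional + self.n_sporadic


# peak months alternate between a warm (May-Aug) and a cool (Nov-Feb) seasonal
# group, mirroring the two host-linked subnetworks of seasonal phages
_WARM_PEAKS = (5, 6, 7, 8)
_COOL_PEAKS = (11, 12, 1, 2)


def _species_specs(
    config: SimulationConfig, baseline_ss: np.random.SeedSequence
) -> tuple[list[str], list[ArchetypeSpec]]:
    # lognormal rank-abundance tail: per-species baseline offsets
    rng = np.random.default_rng(baseline_ss)
    offsets = rng.normal(0.0, config.species_log_sd, size=config.n_species)
    ids, specs = [], []
    i = 0
    plan = [
        ("seasonal", config.n_seasonal),
        ("persistent", config.n_persistent),
        ("occasional", config.n_occasional),
        ("sporadic", config.n_sporadic),
    ]
    for arch, n in plan:
        for j in range(n):
            sid = f"sp{i:04d}"
            if arch == "seasonal":
                peaks = _WARM_PEAKS if j % 2 == 0 else _COOL_PEAKS
                spec = ArchetypeSpec(
                    "seasonal",
                    peak_month=peaks[(j // 2) % len(peaks)],
                    baseline_log_abundance=config.baseline_seasonal + offsets[i],
                    seasonal_amplitude=config.seasonal_amplitude,
                    noise_sd=config.noise_sd,
                    season_width=config.season_width,
                )
            elif arch == "persistent":
                spec = ArchetypeSpec(
                    "persistent",
                    baseline_log_abundance=config.baseline_persistent + offsets[i],
                    noise_sd=config.noise_sd,
                )
            elif arch == "occasional":
                spec = ArchetypeSpec(
                    "occasional",
                    baseline_log_abundance=config.baseline_occasional + offsets[i],
                    occurrence_prob=config.occurrence_occasional,
                    noise_sd=config.noise_sd,
                )
            else:
                spec = ArchetypeSpec(
                    "sporadic",
                    baseline_log_abundance=config.baseline_sporadic + offsets[i],
                    occurrence_prob=config.occurrence_sporadic,
                    noise_sd=config.noise_sd,
                )
            ids.append(sid)
            specs.append(spec)
            i += 1
    return ids, specs


def _coverage_from_counts(
    counts: pd.DataFrame, gene_length: pd.Series, read_length: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lander-Waterman expected coverage from read counts.

    mean depth = reads * read_length / gene_length; base coverage is
    1 - exp(-depth), rounded up to exactly 1.0 once the expected number of
    uncovered bases drops below half a base.
    """
    L = gene_length.to_numpy()[:, None].astype(float)
    depth = counts.to_numpy() * read_length / L
    cov = 1.0 - np.exp(-depth)
    cov[L * np.exp(-depth) < 0.5] = 1.0
    cov[depth == 0] = 0.0
    return (
        pd.DataFrame(cov, index=counts.index, columns=counts.columns),
        pd.DataFrame(depth, index=counts.index, columns=counts.columns),
    )


def _multinomial_counts(
    latent: np.ndarray, library_size: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw per-month multinomial read counts from latent relative abundances."""
    n_sp, n_m = latent.shape
    out = np.zeros((n_sp, n_m), dtype=np.int64)
    for j in range(n_m):
        tot = latent[:, j].sum()
        if tot <= 0:
            continue
        out[:, j] = rng.multinomial(library_size, latent[:, j] / tot)
    return out


def _random_sequences(ids: list[str], length: int, ss: np.random.SeedSequence) -> dict[str, str]:
    rng = np.random.default_rng(ss)
    alphabet = np.array(list("ACGT"))
    return {sid: "".join(rng.choice(alphabet, size=length)) for sid in ids}


def simulate_dataset(config: SimulationConfig, seed: int) -> SyntheticDataset:
    """Generate a fully labeled synthetic two-fraction community survey."""
    if config.n_species == 0:
        raise ValueError("at least one species is required")
    if config.library_size_viral <= 0 or config.library_size_cellular <= 0:
        raise ValueError("library sizes must be > 0")

    root = np.random.SeedSequence(seed)
    streams = root.spawn(8)
    months = pd.period_range(config.start_month, periods=config.n_months, freq="M")
    moy = np.array([m.month for m in months], dtype=float)

    ids, specs = _species_specs(config, streams[_STREAM_BASELINES])
    traj_streams = streams[_STREAM_TRAJ].spawn(len(ids))
    latent = np.vstack(
        [simulate_trajectory(sp, months, ssq) for sp, ssq in zip(specs, traj_streams)]
    )

    # missing months, completely at random
    rng_miss = np.random.default_rng(streams[_STREAM_MISSING])
    missing = rng_miss.random(config.n_months) < config.missing_prob
    sampled = months[~missing]
    sampled_cols = [str(m) for m in sampled]

    # cellular fraction sees the same latent community through independent
    # per-species-month lognormal distortion (optionally lagged)
    rng_counts = np.random.default_rng(streams[_STREAM_COUNTS])
    frac_noise = rng_counts.normal(0.0, config.fraction_noise_sd, size=latent.shape)
    latent_cell = np.roll(latent, config.host_lag_months, axis=1) * np.exp(frac_noise)

    counts_v = _multinomial_counts(latent[:, ~missing], config.library_size_viral, rng_counts)
    counts_c = _multinomial_counts(
        latent_cell[:, ~missing], config.library_size_cellular, rng_counts
    )

    rng_genes = np.random.default_rng(streams[_STREAM_GENES])
    gene_length = pd.Series(
        rng_genes.integers(*config.gene_length_range, size=len(ids)), index=ids, name="gene_length"
    )

    def _table(counts: np.ndarray, lib: int, label: str) -> SpeciesCountTable:
        df = pd.DataFrame(counts, index=ids, columns=sampled_cols)
        cov, depth = _coverage_from_counts(df, gene_length, config.read_length)
        return SpeciesCountTable(
            counts=df,
            gene_length=gene_length,
            library_size=pd.Series(lib, index=sampled_cols, name="library_size"),
            base_coverage=cov,
            mean_depth=depth,
            fraction_label=label,
        )

    table_v = _table(counts_v, config.library_size_viral, "viral")
    table_c = _table(counts_c, config.library_size_cellular, "cellular")

    # hosts: coupled ASV-like taxa track one seasonal phage's latent signal;
    # two ecotype-like taxa track the warm and cool seasonal groups; a few
    # uncoupled taxa are lognormal noise
    rng_host = np.random.default_rng(streams[_STREAM_HOSTS])
    seasonal_ids = [i for i, sp in zip(ids, specs) if sp.archetype == "seasonal"]
    seasonal_idx = {i: k for k, i in enumerate(ids)}
    c = config.host_coupling_strength
    host_rows, host_names, linked = {}, [], {}
    n_coupled = min(config.n_coupled_hosts, len(seasonal_ids))
    for h in range(n_coupled):
        sid = seasonal_ids[h]
        sig = latent[seasonal_idx[sid]]
        sig = np.roll(sig, config.host_lag_months)
        norm = sig / sig.max() if sig.max() > 0 else sig
        series = 1e4 * (c * norm + (1 - c) * 0.5) * np.exp(
            rng_host.normal(0.0, 0.2, size=len(months))
        )
        name = f"asv{h:03d}"
        host_rows[name] = series
        host_names.append(name)
        linked[sid] = name
    for grp, peaks in (("eco_warm", _WARM_PEAKS), ("eco_cool", _COOL_PEAKS)):
        members = [
            i
            for i, sp in zip(ids, specs)
            if sp.archetype == "seasonal" and sp.peak_month in peaks
        ]
        sig = latent[[seasonal_idx[i] for i in members]].sum(axis=0)
        norm = sig / sig.max() if sig.max() > 0 else sig
        host_rows[grp] = 5e4 * (c * norm + (1 - c) * 0.5) * np.exp(
            rng_host.normal(0.0, 0.2, size=len(months))
        )
    for h in range(config.n_uncoupled_hosts):
        host_rows[f"asv_bg{h:03d}"] = 5e3 * np.exp(
            rng_host.normal(0.0, 0.5, size=len(months))
        )
    host = pd.DataFrame(host_rows).T
    host.columns = [str(m) for m in months]
    host = host[sampled_cols]

    # environmental covariates: two seasonal drivers, one deterministic
    # photoperiod, two noise covariates
    rng_env = np.random.default_rng(streams[_STREAM_ENV])
    env = pd.DataFrame(
        {
            "temperature": 15 + 5 * np.cos(2 * np.pi * (moy - 8) / 12)
            + rng_env.normal(0, 0.5, len(months)),
            "day_length": 12 + 2.4 * np.cos(2 * np.pi * (moy - 6) / 12),
            "mixed_layer_depth": 25 + 10 * np.cos(2 * np.pi * (moy - 1) / 12)
            + rng_env.normal(0, 2.0, len(months)),
            "salinity": 33.5 + rng_env.normal(0, 0.1, len(months)),
            "nitrate": np.exp(rng_env.normal(0, 0.5, len(months))),
        }
    ).T
    env.columns = [str(m) for m in months]
    env = env[sampled_cols]

    truth = pd.DataFrame(
        {
            "species": ids,
            "archetype": [sp.archetype for sp in specs],
            "peak_month": [sp.peak_month if sp.archetype == "seasonal" else pd.NA for sp in specs],
            "linked_host": [linked.get(i, pd.NA) for i in ids],
        }
    ).set_index("species")

    sequences = _random_sequences(ids, config.marker_length, streams[_STREAM_FASTA])

    return SyntheticDataset(
        counts_viral=table_v,
        counts_cellular=table_c,
        host_abundance=host,
        env=env,
        truth=truth,
        months=months,
        missing=pd.Series(missing, index=[str(m) for m in months], name="missing"),
        sequences=sequences,
        seed=seed,
    )


def config_from_dict(d: dict) -> SimulationConfig:
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    extra = set(d) - known
    if extra:
        raise ValueError(f"unknown simulation config keys: {sorted(extra)}")
    if "gene_length_range" in d:
        d = dict(d, gene_length_range=tuple(d["gene_length_range"]))
    return SimulationConfig(**d)
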