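"""Allele-frequency data handling.

Reads genotype/frequency tables, applies missing-data filters, and computes
the two empirical inputs to the covariance model: the allelic covariance
matrix between samples and the pairwise geographic distance matrix.

The allelic covariance between samples ``i`` and ``j`` is the covariance of
single-allele indicator variables drawn with a randomized reference allele.
Off the diagonal it is estimated from reference-allele frequencies ``f`` as

    omega_hat[i, j] = mean over loci of (f[i] - 1/2) * (f[j] - 1/2)

while the diagonal is the indicator variance, exactly 1/4, because each
indicator is marginally a fair coin.  The statistic is invariant to which
allele is labelled "reference" at each locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FrequencyMatrix",
    "AllelicCovariance",
    "DistanceMatrix",
    "FilterReport",
    "read_frequencies",
    "read_coordinates",
    "filter_missing",
    "filter_singletons",
    "allelic_covariance",
    "covariance_from_pi",
    "pairwise_distances",
    "write_frequencies",
]

EARTH_RADIUS_KM = 6371.0


class ParseError(ValueError):
    """Raised when an input table is malformed."""


@dataclass
class FrequencyMatrix:
    """Per-sample reference-allele frequencies at biallelic loci.

    Attributes
    ----------
    frequencies : (N, L) float array
        Frequency of the reference allele per sample per locus; entries under
        the missing mask are NaN.
    missing_mask : (N, L) bool array
        True where the observation is missing.
    sample_ids : list of str
    locus_ids : list of str
    ploidy_counts : (N,) int array or None
        Haploid allele counts behind each sample (documentation only).
    """

    frequencies: np.ndarray
    missing_mask: np.ndarray = None
    sample_ids: list = None
    locus_ids: list = None
    ploidy_counts: np.ndarray = None

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.frequencies.ndim != 2:
            raise ValueError("frequencies must be a 2-D (samples x loci) array")
        n, l = self.frequencies.shape
        if n < 2:
            raise ValueError(f"need at least 2 samples, got {n}")
        if l < 1:
            raise ValueError("need at least 1 locus")
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.frequencies)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != (n, l):
            raise ValueError("missing_mask shape does not match frequencies")
        if self.sample_ids is None:
            self.sample_ids = [f"sample_{i}" for i in range(n)]
        if self.locus_ids is None:
            self.locus_ids = [f"locus_{j}" for j in range(l)]
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match frequencies")
        if len(self.locus_ids) != l:
            raise ValueError("locus_ids length does not match frequencies")
        if self.ploidy_counts is not None:
            self.ploidy_counts = np.asarray(self.ploidy_counts, dtype=int)
            if self.ploidy_counts.shape != (n,):
                raise ValueError("ploidy_counts length does not match samples")
            if np.any(self.ploidy_counts < 1):
                raise ValueError("ploidy_counts must be positive")
        obs = self.frequencies[~self.missing_mask]
        if obs.size and (np.nanmin(obs) < -1e-12 or np.nanmax(obs) > 1 + 1e-12):
            raise ValueError("non-missing frequencies must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.frequencies.shape[0]

    @property
    def n_loci(self) -> int:
        return self.frequencies.shape[1]


@dataclass
class AllelicCovariance:
    """Empirical allelic covariance omega_hat with its locus count.

    The diagonal is fixed at exactly 1/4 (variance of a fair-coin indicator);
    off-diagonal entries lie in [-1/4, 1/4].
    """

    omega_hat: np.ndarray
    n_loci: int
    pair_loci: np.ndarray = None  # per-pair locus counts under pairwise policy

    def __post_init__(self):
        self.omega_hat = np.asarray(self.omega_hat, dtype=float)
        m = self.omega_hat
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("omega_hat must be square")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("omega_hat must be symmetric")
        if not np.all(np.diag(m) == 0.25):
            raise ValueError("omega_hat diagonal must be exactly 1/4")
        off = m[~np.eye(m.shape[0], dtype=bool)]
        if off.size and (off.min() < -0.25 - 1e-9 or off.max() > 0.25 + 1e-9):
            raise ValueError("off-diagonal allelic covariance must be in [-1/4, 1/4]")
        if int(self.n_loci) < 1:
            raise ValueError("n_loci must be >= 1")
        self.n_loci = int(self.n_loci)

    @property
    def n_samples(self) -> int:
        return self.omega_hat.shape[0]


@dataclass
class DistanceMatrix:
    """Pairwise geographic distances, optionally rescaled to mean 1."""

    d: np.ndarray
    metric_tag: str = "euclidean"
    scale_factor: float = 1.0

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        if self.d.ndim != 2 or self.d.shape[0] != self.d.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(self.d, self.d.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be nonnegative")
        if not self.scale_factor > 0:
            raise ValueError("scale_factor must be positive")

    @property
    def n_samples(self) -> int:
        return self.d.shape[0]


@dataclass
class FilterReport:
    n_samples_removed: int
    n_loci_removed: int
    removed_sample_ids: list = field(default_factory=list)


def _split_rows(path) -> list:
    """Raw rows as lists of string fields; ragged rows are preserved so
    dimension errors can name the offending line."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if "," in line:
                fields = [f.strip() for f in line.split(",")]
            elif "\t" in line:
                fields = [f.strip() for f in line.split("\t")]
            else:
                fields = line.split()
            rows.append(fields)
    return rows


def read_frequencies(path, format_tag: str = "delimited-frequencies",
                     ploidy: int = 1, missing_code: str = "-9") -> FrequencyMatrix:
    """Read a frequency or genotype table into a :class:`FrequencyMatrix`.

    Parameters
    ----------
    path : str or Path
        Delimited text file (comma, tab or whitespace separated).
    format_tag : {"delimited-frequencies", "structure-genotypes"}
        ``delimited-frequencies``: header row of locus IDs, first column a
        sample ID.  With ``ploidy == 1`` values are frequencies in [0, 1]
        (or NA); with ``ploidy > 1`` values are reference-allele counts in
        ``{0, ..., ploidy}`` and are converted to frequencies as
        count / ploidy.
        ``structure-genotypes``: one row per haploid allele copy, ``ploidy``
        consecutive rows per individual sharing a sample ID in the first
        column, integer allele codes, missing entries coded ``missing_code``.
        The reference allele at each locus is the first non-missing allele
        observed; downstream statistics are invariant to that choice.
    ploidy : int
        Allele copies per individual.
    missing_code : str
        Missing-genotype code for the STRUCTURE-style format (default "-9").
    """
    if ploidy < 1:
        raise ValueError("ploidy must be a positive integer")
    if format_tag == "delimited-frequencies":
        return _read_delimited(path, ploidy)
    if format_tag == "structure-genotypes":
        return _read_structure(path, ploidy, missing_code)
    raise ValueError(f"unknown format_tag {format_tag!r}")


def _read_delimited(path, ploidy: int) -> FrequencyMatrix:
    raw = _split_rows(path)
    if len(raw) < 2:
        raise ParseError(f"{path}: expected a header row plus data rows")
    locus_ids = [str(v) for v in raw[0][1:]]
    sample_ids = [str(r[0]) for r in raw[1:]]
    n_loci = len(locus_ids)
    rows = []
    for r, fields in enumerate(raw[1:]):
        vals = fields[1:]
        if len(vals) != n_loci:
            raise ParseError(
                f"{path}: row {r + 2} (sample {sample_ids[r]!r}) has "
                f"{len(vals)} entries, expected {n_loci}")
        parsed = np.empty(n_loci)
        for c, v in enumerate(vals):
            if str(v).strip().upper() in {"NA", "NAN", ""}:
                parsed[c] = np.nan
                continue
            try:
                x = float(v)
            except ValueError:
                raise ParseError(
                    f"{path}: row {r + 2}, column {c + 2}: "
                    f"cannot parse {v!r}") from None
            if ploidy > 1:
                if not (x.is_integer() and 0 <= x <= ploidy):
                    raise ParseError(
                        f"{path}: row {r + 2}, column {c + 2}: genotype {v!r} "
                        f"outside {{0..{ploidy}}}")
                x /= ploidy
            elif not 0 <= x <= 1:
                raise ParseError(
                    f"{path}: row {r + 2}, column {c + 2}: frequency {v!r} "
                    "outside [0, 1]")
            parsed[c] = x
        rows.append(parsed)
    freqs = np.array(rows)
    return FrequencyMatrix(freqs, np.isnan(freqs), sample_ids, locus_ids,
                           np.full(len(sample_ids), ploidy))


def _read_structure(path, ploidy: int, missing_code: str) -> FrequencyMatrix:
    raw = _split_rows(path)
    n_rows = len(raw)
    if n_rows == 0:
        raise ParseError(f"{path}: empty file")
    if n_rows % ploidy:
        raise ParseError(
            f"{path}: {n_rows} rows is not a multiple of ploidy {ploidy}")
    n_loci = len(raw[0]) - 1
    if n_loci < 1:
        raise ParseError(f"{path}: no locus columns found")
    alleles = np.empty((n_rows, n_loci))
    for r, fields in enumerate(raw):
        if len(fields) - 1 != n_loci:
            raise ParseError(
                f"{path}: row {r + 1} has {len(fields) - 1} loci, "
                f"expected {n_loci}")
        for c in range(n_loci):
            v = str(fields[c + 1]).strip()
            if v == missing_code or v.upper() in {"NA", "NAN"}:
                alleles[r, c] = np.nan
                continue
            try:
                alleles[r, c] = float(v)
            except ValueError:
                raise ParseError(
                    f"{path}: row {r + 1}, column {c + 2}: "
                    f"cannot parse allele {v!r}") from None
    sample_ids = []
    for i in range(0, n_rows, ploidy):
        ids = {str(raw[r][0]) for r in range(i, i + ploidy)}
        if len(ids) != 1:
            raise ParseError(
                f"{path}: rows {i + 1}-{i + ploidy} mix sample IDs {sorted(ids)}")
        sample_ids.append(ids.pop())
    # reference allele per locus: first non-missing allele code observed
    freqs = np.full((len(sample_ids), n_loci), np.nan)
    for c in range(n_loci):
        col = alleles[:, c]
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            continue  # fully missing locus: stays masked everywhere
        codes = np.unique(obs)
        if codes.size > 2:
            raise ParseError(
                f"{path}: column {c + 2} has {codes.size} alleles; "
                "loci must be biallelic")
        ref = obs[0]
        for s in range(len(sample_ids)):
            copies = col[s * ploidy:(s + 1) * ploidy]
            seen = copies[~np.isnan(copies)]
            if seen.size:
                freqs[s, c] = np.mean(seen == ref)
    return FrequencyMatrix(freqs, np.isnan(freqs), sample_ids,
                           [f"locus_{j}" for j in range(n_loci)],
                           np.full(len(sample_ids), ploidy))


def read_coordinates(path, sample_ids=None) -> np.ndarray:
    """Read a coordinates table (sample_id, x/lon, y/lat) -> (N, 2) array.

    If ``sample_ids`` is given, rows are matched and reordered by ID.
    """
    df = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str,
                     comment="#", skip_blank_lines=True)
    first = df.iloc[0]
    try:  # drop a header row if the coordinate columns don't parse
        float(first.iloc[1]), float(first.iloc[2])
    except (ValueError, TypeError):
        df = df.iloc[1:]
    ids = [str(v) for v in df.iloc[:, 0]]
    coords = df.iloc[:, 1:3].astype(float).to_numpy()
    if sample_ids is not None:
        index = {s: i for i, s in enumerate(ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise ParseError(f"{path}: no coordinates for samples {missing}")
        coords = coords[[index[s] for s in sample_ids]]
    return coords


def write_frequencies(fm: FrequencyMatrix, path) -> None:
    """Write the delimited frequency format that :func:`read_frequencies` reads."""
    df = pd.DataFrame(fm.frequencies, index=fm.sample_ids, columns=fm.locus_ids)
    df[fm.missing_mask] = np.nan
    df.to_csv(path, index_label="sample_id", na_rep="NA")


def filter_missing(fm: FrequencyMatrix, locus_policy: str = "drop-any-missing",
                   sample_missing_threshold: float | None = None):
    """Remove high-missingness samples, then (optionally) incomplete loci.

    Samples whose missing fraction is *strictly greater* than
    ``sample_missing_threshold`` are removed first.  Then, under
    ``locus_policy="drop-any-missing"``, every locus still missing in any
    retained sample is dropped; ``"keep"`` leaves loci untouched.

    Returns ``(FrequencyMatrix, FilterReport)``.
    """
    if locus_policy not in {"drop-any-missing", "keep"}:
        raise ValueError(f"unknown locus_policy {locus_policy!r}")
    keep_s = np.ones(fm.n_samples, dtype=bool)
    if sample_missing_threshold is not None:
        if not 0 <= sample_missing_threshold <= 1:
            raise ValueError("sample_missing_threshold must be in [0, 1]")
        frac = fm.missing_mask.mean(axis=1)
        keep_s = frac <= sample_missing_threshold  # strict ">" removes
    if keep_s.sum() == 0:
        raise ValueError("all samples removed by missing-data filter")
    mask = fm.missing_mask[keep_s]
    keep_l = np.ones(fm.n_loci, dtype=bool)
    if locus_policy == "drop-any-missing":
        keep_l = ~mask.any(axis=0)
        if keep_l.sum() == 0:
            raise ValueError("all loci removed by missing-data filter")
    report = FilterReport(
        n_samples_removed=int((~keep_s).sum()),
        n_loci_removed=int((~keep_l).sum()),
        removed_sample_ids=[s for s, k in zip(fm.sample_ids, keep_s) if not k],
    )
    out = FrequencyMatrix(
        fm.frequencies[np.ix_(keep_s, keep_l)],
        fm.missing_mask[np.ix_(keep_s, keep_l)],
        [s for s, k in zip(fm.sample_ids, keep_s) if k],
        [l for l, k in zip(fm.locus_ids, keep_l) if k],
        None if fm.ploidy_counts is None else fm.ploidy_counts[keep_s],
    )
    return out, report


def filter_singletons(fm: FrequencyMatrix, tol: float = 1e-12):
    """Drop loci where the minor allele appears in exactly one sample.

    Allelic covariance is more sensitive to singleton sites than the standard
    genetic covariance, so sequencing errors concentrated there can bias it;
    this optional filter removes loci whose non-modal frequency value occurs
    in a single sample.  Off by default in all pipelines.
    """
    f = np.ma.masked_array(fm.frequencies, fm.missing_mask)
    keep = np.ones(fm.n_loci, dtype=bool)
    for j in range(fm.n_loci):
        col = f[:, j].compressed()
        if col.size < 2:
            continue
        # a singleton: all samples share one value except exactly one sample
        vals, counts = np.unique(np.round(col / tol) * tol if tol else col,
                                 return_counts=True)
        if vals.size == 2 and counts.min() == 1:
            keep[j] = False
    if keep.sum() == 0:
        raise ValueError("all loci removed by singleton filter")
    out = FrequencyMatrix(fm.frequencies[:, keep], fm.missing_mask[:, keep],
                          fm.sample_ids,
                          [l for l, k in zip(fm.locus_ids, keep) if k],
                          fm.ploidy_counts)
    return out, FilterReport(0, int((~keep).sum()))


def allelic_covariance(fm: FrequencyMatrix,
                       missing_policy: str = "complete-case") -> AllelicCovariance:
    """Empirical allelic covariance matrix from a frequency matrix.

    Off-diagonal entries are the mean over loci of
    ``(f_i - 1/2)(f_j - 1/2)``; the diagonal is set to exactly 1/4.  Under
    ``"complete-case"`` no missing entries may remain; ``"pairwise"`` uses,
    for each pair, the loci observed in both samples (note this breaks the
    single-locus-count Wishart assumption; per-pair counts are recorded).
    """
    n = fm.n_samples
    if missing_policy == "complete-case":
        if fm.missing_mask.any():
            raise ValueError(
                "complete-case allelic covariance requires no missing data; "
                "run filter_missing first")
        dev = fm.frequencies - 0.5
        omega = dev @ dev.T / fm.n_loci
        pair_counts = np.full((n, n), fm.n_loci)
        n_used = fm.n_loci
    elif missing_policy == "pairwise":
        obs = ~fm.missing_mask
        dev = np.where(obs, fm.frequencies - 0.5, 0.0)
        cross = dev @ dev.T
        pair_counts = obs.astype(float) @ obs.T.astype(float)
        bad = np.argwhere((pair_counts == 0) & ~np.eye(n, dtype=bool))
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"samples {fm.sample_ids[i]!r} and {fm.sample_ids[j]!r} share "
                "no non-missing loci")
        with np.errstate(invalid="ignore", divide="ignore"):
            omega = cross / np.maximum(pair_counts, 1)
        pair_counts = pair_counts.astype(int)
        off = pair_counts[~np.eye(n, dtype=bool)]
        n_used = int(off.min()) if off.size else fm.n_loci
    else:
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    omega = (omega + omega.T) / 2.0
    np.fill_diagonal(omega, 0.25)
    return AllelicCovariance(omega, n_used, pair_loci=pair_counts)


def covariance_from_pi(pi: np.ndarray, n_loci: int = 1) -> AllelicCovariance:
    """Allelic covariance from a pairwise genetic-distance matrix.

    Off the diagonal, ``omega = (1 - 2 * pi) / 4`` where ``pi`` is the
    proportion of sites at which random alleles from the two samples differ;
    the diagonal is 1/4 (``pi = 0`` against oneself by definition here).
    """
    pi = np.asarray(pi, dtype=float)
    if pi.ndim != 2 or pi.shape[0] != pi.shape[1]:
        raise ValueError("pi must be square")
    if not np.allclose(pi, pi.T, atol=1e-12):
        raise ValueError("pi must be symmetric")
    if np.any(np.diag(pi) != 0):
        raise ValueError("pi must have a zero diagonal")
    if pi.min() < 0 or pi.max() > 1:
        raise ValueError("pi entries must lie in [0, 1]")
    omega = (1.0 - 2.0 * pi) / 4.0
    np.fill_diagonal(omega, 0.25)
    return AllelicCovariance(omega, n_loci)


def pairwise_distances(coords: np.ndarray, metric: str = "euclidean",
                       normalize: bool = True) -> DistanceMatrix:
    """Pairwise geographic distances between sample coordinates.

    ``metric="great-circle"`` treats columns as (lon, lat) in decimal degrees
    and returns haversine distances on a sphere of radius 6371 km;
    ``"euclidean"`` treats them as planar.  With ``normalize=True`` (default)
    the matrix is divided by its mean off-diagonal entry so the mean pairwise
    distance is 1; the divisor is recorded as ``scale_factor`` so fitted
    inverse-distance scales can be reported in original units.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be an (N, 2) array")
    if metric == "euclidean":
        from scipy.spatial.distance import pdist, squareform
        d = squareform(pdist(coords))
    elif metric == "great-circle":
        lon, lat = coords[:, 0], coords[:, 1]
        if np.any(np.abs(lat) > 90):
            raise ValueError("latitude outside [-90, 90]")
        if np.any(np.abs(lon) > 360):
            raise ValueError("longitude outside [-360, 360]")
        lam, phi = np.radians(lon), np.radians(lat)
        dphi = phi[:, None] - phi[None, :]
        dlam = lam[:, None] - lam[None, :]
        a = (np.sin(dphi / 2) ** 2
             + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2)
        d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
        np.fill_diagonal(d, 0.0)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    d = (d + d.T) / 2.0
    scale = 1.0
    if normalize:
        off = d[~np.eye(d.shape[0], dtype=bool)]
        mean = off.mean() if off.size else 0.0
        if mean > 0:
            d = d / mean
            scale = float(mean)
    return DistanceMatrix(d, metric_tag=metric, scale_factor=scale)
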