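"""Mutational-signature catalogues, exposure refitting and APOBEC analyses.

The exposure fitter follows the greedy forward-selection scheme popularised
for signature refitting in targeted/exome data: starting from an empty
exposure vector it repeatedly adds the single signature whose best weight
(golden-section line search on [0, 1]) most reduces the squared error
between the normalised catalogue and the exposure-weighted signature mix,
renormalising exposures to sum at most 1, until the relative improvement
falls below ``tol``; weights below the discard threshold are then zeroed
and the surviving signatures re-fitted.

The model/results split mirrors the statsmodels idiom:

>>> result = SignatureDeconvolution(catalogue, signatures).fit()
>>> result.weights        # per-signature exposures, a pandas Series
>>> print(result.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .channels import CHANNELS, channel_label, is_apobec_site, snv_channel
from .io import Cohort, VariantCall
from .stats import fisher_exact_2x2

N_CHANNELS = 96
_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


# ---------------------------------------------------------------------------
# Catalogues and signature matrices
# ---------------------------------------------------------------------------

@dataclass
class MutationCatalogue:
    """Counts over the 96 strand-collapsed trinucleotide channels."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_CHANNELS,):
            raise ValueError(f"catalogue must have {N_CHANNELS} channels")
        if np.any(self.counts < 0):
            raise ValueError("catalogue counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_channels(cls, channels) -> "MutationCatalogue":
        """Build from an iterable of channel indices."""
        idx = np.asarray(list(channels), dtype=np.int64)
        if idx.size and (idx.min() < 0 or idx.max() >= N_CHANNELS):
            raise ValueError("channel indices out of range")
        return cls(np.bincount(idx, minlength=N_CHANNELS))

    @classmethod
    def from_variants(cls, variants) -> "MutationCatalogue":
        """Build from SNV calls carrying a reference trinucleotide context.

        Non-SNVs and SNVs without a context are skipped (they have no
        channel); strand is collapsed automatically.
        """
        idx = [
            snv_channel(v.ref_allele, v.alt_allele, v.context3)
            for v in variants
            if v.is_snv and v.context3 is not None
        ]
        return cls.from_channels(idx)

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(CHANNELS), name="count")

    def normalised(self) -> np.ndarray:
        if self.total == 0:
            raise ValueError("cannot normalise an empty catalogue")
        return self.counts / self.total

    def write_tsv(self, path) -> None:
        self.to_series().rename_axis("channel").reset_index().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "MutationCatalogue":
        df = pd.read_csv(path, sep="\t", comment="#")
        counts = df.set_index("channel")["count"].reindex(list(CHANNELS))
        if counts.isna().any():
            raise ValueError(f"{path}: missing channels in catalogue")
        return cls(counts.to_numpy())


@dataclass
class SignatureMatrix:
    """A 96 x K matrix of reference signatures (columns sum to 1)."""

    names: list[str]
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (N_CHANNELS, len(self.names)):
            raise ValueError("signature matrix must be 96 x len(names)")
        if np.any(self.probs < 0):
            raise ValueError("signature probabilities must be non-negative")
        sums = self.probs.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError(f"signature columns must sum to 1 (got {sums})")

    @property
    def k(self) -> int:
        return len(self.names)

    def subset(self, names) -> "SignatureMatrix":
        idx = [self.names.index(n) for n in names]
        return SignatureMatrix(list(names), self.probs[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probs, index=list(CHANNELS), columns=self.names)


def read_signature_matrix(path) -> SignatureMatrix:
    """Read a signature matrix in the COSMIC v2 probabilities-table layout.

    Expects tab-separated columns ``Substitution Type``, ``Trinucleotide``
    (or a single ``Somatic Mutation Type`` / ``channel`` label column)
    followed by one column per signature; rows may be in any order.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = {c.strip().lower(): c for c in df.columns}
    if "substitution type" in cols and "trinucleotide" in cols:
        labels = [
            f"{tri[0]}[{sub}]{tri[2]}"
            for sub, tri in zip(df[cols["substitution type"]], df[cols["trinucleotide"]])
        ]
        drop = [cols["substitution type"], cols["trinucleotide"]]
        if "somatic mutation type" in cols:
            drop.append(cols["somatic mutation type"])
    elif "somatic mutation type" in cols or "channel" in cols:
        label_col = cols.get("somatic mutation type", cols.get("channel"))
        labels = df[label_col].tolist()
        drop = [label_col]
    else:
        raise ValueError(f"{path}: unrecognised signature-matrix layout")
    data = df.drop(columns=drop)
    data.index = labels
    data = data.reindex(list(CHANNELS))
    if data.isna().any().any():
        raise ValueError(f"{path}: signature matrix is missing channels")
    return SignatureMatrix(list(data.columns), data.to_numpy())


def synthetic_signatures() -> SignatureMatrix:
    """A synthetic five-signature reference set for tests and simulations.

    This is a constructed stand-in, not the COSMIC catalogue (which is an
    input file, never bundled).  The columns are named by role analogy:

    * ``Signature 1`` — ageing-like, C>T at NpCpG;
    * ``Signature 2`` — APOBEC-like C>T at TpCpW;
    * ``Signature 3`` — flat (HR-deficiency-like);
    * ``Signature 5`` — broad with a T>C lean;
    * ``Signature 13`` — APOBEC-like C>G (plus some C>A) at the APOBEC
      consensus trinucleotides, so consensus-site enrichment maps onto it.
    """
    channels = list(CHANNELS)

    def peaked(mass_map: dict[str, float], floor_mass: float) -> np.ndarray:
        col = np.full(N_CHANNELS, floor_mass / N_CHANNELS)
        for label, mass in mass_map.items():
            col[channels.index(label)] += mass
        return col / col.sum()

    sig1 = peaked({f"{f}[C>T]G": 0.85 / 4 for f in "ACGT"}, 0.15)
    sig2 = peaked({"T[C>T]A": 0.45, "T[C>T]T": 0.45}, 0.10)
    sig3 = np.full(N_CHANNELS, 1.0 / N_CHANNELS)
    tc_lean = {f"{f}[T>C]{t}": 0.5 / 16 for f in "ACGT" for t in "ACGT"}
    sig5 = peaked(tc_lean, 0.5)
    sig13 = peaked(
        {
            "T[C>G]T": 0.35,
            "T[C>G]A": 0.35,
            **{f"T[C>A]{t}": 0.25 / 4 for t in "ACGT"},
        },
        0.05,
    )
    probs = np.column_stack([sig1, sig2, sig3, sig5, sig13])
    names = ["Signature 1", "Signature 2", "Signature 3", "Signature 5", "Signature 13"]
    return SignatureMatrix(names, probs)


# ---------------------------------------------------------------------------
# Clonal / subclonal aggregation
# ---------------------------------------------------------------------------

@dataclass
class MutationSet:
    """Deduplicated SNV sites behind a catalogue (one record per site)."""

    sites: list[tuple[str, int, str, str]]
    channels: np.ndarray

    def catalogue(self) -> MutationCatalogue:
        return MutationCatalogue.from_channels(self.channels)

    def __len__(self) -> int:
        return len(self.sites)


@dataclass
class ClonalSubclonalSets:
    clonal: MutationSet
    subclonal: MutationSet


def aggregate_clonal_subclonal(cohort: Cohort, subtype: str | None = None) -> ClonalSubclonalSets:
    """Aggregate SNVs into clonal and subclonal mutation sets for a subtype.

    All SNVs with a trinucleotide context enter, regardless of
    pathogenicity.  Each mutation site (chrom, pos, ref, alt) is counted
    once per set; a site that is dominant in one patient and subclonal in
    another contributes once to each set.  Variants without an assessable
    cancer fraction contribute to neither.
    """
    from .clonality import annotate_clonality  # local import to avoid a cycle

    buckets: dict[str, dict[tuple, int]] = {"dominant": {}, "subclonal": {}}
    for profile in cohort:
        if subtype is not None and profile.subtype != subtype:
            continue
        for v, ann in zip(profile.variants, annotate_clonality(profile)):
            if ann.dominance == "not_assessable":
                continue
            if not (v.is_snv and v.context3 is not None):
                continue
            key = v.site_key
            buckets[ann.dominance].setdefault(
                key, snv_channel(v.ref_allele, v.alt_allele, v.context3)
            )

    def build(bucket: dict[tuple, int]) -> MutationSet:
        sites = sorted(bucket)
        return MutationSet(sites, np.array([bucket[s] for s in sites], dtype=np.int64))

    return ClonalSubclonalSets(build(buckets["dominant"]), build(buckets["subclonal"]))


# ---------------------------------------------------------------------------
# Exposure fitting (model / results)
# ---------------------------------------------------------------------------

def _greedy_fit(
    target: np.ndarray,
    probs: np.ndarray,
    tol: float,
    line_search_tol: float,
    max_rounds: int = 200,
) -> np.ndarray:
    """Greedy forward-selection exposures for a normalised catalogue.

    Each round evaluates, for every candidate signature, the best single
    weight on [0, 1] by golden-section search (vectorised across
    candidates); exposures exceeding a total of 1 are renormalised by their
    sum.  Stops when the relative squared-error improvement drops below
    ``tol``.
    """
    k = probs.shape[1]
    exposures = np.zeros(k)
    sse = float(target @ target)

    # Along the line search the SSE reduces to scalar arithmetic on
    # precomputed inner products, so no 96-vector work is done per step.
    cc = float(target @ target)
    cS = (target @ probs).tolist()                  # target . S_j
    SS = np.einsum("ij,ij->j", probs, probs).tolist()  # S_j . S_j
    mixS = [0.0] * k                                 # mix . S_j
    cmix = 0.0                                       # target . mix
    mixmix = 0.0                                     # mix . mix
    total_exposure = 0.0
    golden = float(_GOLDEN)

    for _ in range(max_rounds):
        best_j = -1
        best_w = 0.0
        best_sse = sse
        for j in range(k):
            csj, ssj, msj = cS[j], SS[j], mixS[j]

            def f(w: float) -> float:
                s = total_exposure + w
                if s < 1.0:
                    s = 1.0
                cu = cmix + w * csj
                uu = mixmix + 2.0 * w * msj + w * w * ssj
                return cc - 2.0 * cu / s + uu / (s * s)

            a, b = 0.0, 1.0
            x1 = b - golden * (b - a)
            x2 = a + golden * (b - a)
            f1, f2 = f(x1), f(x2)
            while b - a > line_search_tol:
                if f1 < f2:
                    b, x2, f2 = x2, x1, f1
                    x1 = b - golden * (b - a)
                    f1 = f(x1)
                else:
                    a, x1, f1 = x1, x2, f2
                    x2 = a + golden * (b - a)
                    f2 = f(x2)
            w = 0.5 * (a + b)
            fw = f(w)
            if fw < best_sse:
                best_j, best_w, best_sse = j, w, fw

        if best_j < 0:
            break
        exposures[best_j] += best_w
        total_exposure = float(exposures.sum())
        if total_exposure > 1.0:
            exposures /= total_exposure
            total_exposure = 1.0
        mix = probs @ exposures
        mixS = (mix @ probs).tolist()
        cmix = float(target @ mix)
        mixmix = float(mix @ mix)
        new_sse = float(((target - mix) ** 2).sum())
        if sse > 0 and (sse - new_sse) / sse < tol:
            sse = new_sse
            break
        sse = new_sse
        if sse <= 1e-12:
            break
    return exposures


class SignatureDeconvolution:
    """Non-negative refit of reference signatures to one mutation catalogue.

    Parameters
    ----------
    catalogue : MutationCatalogue
        Observed 96-channel counts (total must be at least 1).
    signatures : SignatureMatrix
        Reference signatures to mix.
    discard_threshold : float
        Exposures below this value are zeroed and the rest re-fitted.
    tol : float
        Stop when the relative squared-error improvement falls below this.
    line_search_tol : float
        Absolute tolerance of the golden-section weight search.
    """

    def __init__(
        self,
        catalogue: MutationCatalogue,
        signatures: SignatureMatrix,
        discard_threshold: float = 0.06,
        tol: float = 1e-3,
        line_search_tol: float = 1e-4,
    ) -> None:
        if catalogue.total < 1:
            raise ValueError("cannot fit exposures to an empty catalogue")
        self.catalogue = catalogue
        self.signatures = signatures
        self.discard_threshold = discard_threshold
        self.tol = tol
        self.line_search_tol = line_search_tol

    def _fit_array(self) -> np.ndarray:
        target = self.catalogue.normalised()
        probs = self.signatures.probs
        exposures = _greedy_fit(target, probs, self.tol, self.line_search_tol)

        keep = exposures >= self.discard_threshold
        if keep.any() and not keep.all():
            refit = _greedy_fit(target, probs[:, keep], self.tol, self.line_search_tol)
            exposures = np.zeros_like(exposures)
            exposures[keep] = refit
        elif not keep.any():
            exposures = np.zeros_like(exposures)
        # weights surviving the threshold but shrunk below it by the refit are zeroed too
        exposures[exposures < self.discard_threshold] = 0.0
        return exposures

    def fit(self) -> "ExposureResult":
        exposures = self._fit_array()
        target = self.catalogue.normalised()
        mix = self.signatures.probs @ exposures
        error = float(((target - mix) ** 2).sum())
        weights = pd.Series(exposures, index=self.signatures.names, name="exposure")
        return ExposureResult(self, weights, 1.0 - float(exposures.sum()), error)


@dataclass
class ExposureResult:
    """Fitted per-signature exposures for one catalogue."""

    model: SignatureDeconvolution
    weights: pd.Series
    residual: float
    reconstruction_error: float

    def summary(self) -> str:
        lines = [
            "Signature exposure refit",
            "=" * 40,
            f"mutations:            {self.model.catalogue.total}",
            f"signatures offered:   {self.model.signatures.k}",
            f"discard threshold:    {self.model.discard_threshold}",
            f"reconstruction SSE:   {self.reconstruction_error:.3e}",
            f"unassigned residual:  {self.residual:.3f}",
            "-" * 40,
        ]
        for name, w in self.weights.items():
            lines.append(f"{name:<20s} {w:8.3f}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Bar plot of the fitted exposures (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 3))
        self.weights.plot.bar(ax=ax, color="#4C72B0")
        ax.set_ylabel("exposure")
        ax.set_ylim(0, 1)
        return ax


def fit_exposures(
    catalogue: MutationCatalogue,
    signatures: SignatureMatrix,
    discard_threshold: float = 0.06,
    tol: float = 1e-3,
) -> ExposureResult:
    """Functional wrapper around :class:`SignatureDeconvolution`."""
    return SignatureDeconvolution(catalogue, signatures, discard_threshold, tol).fit()


# ---------------------------------------------------------------------------
# Bootstrap and condition comparison
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    """Per-signature exposure distributions over bootstrap subsamples."""

    exposures: pd.DataFrame  # n_iter x K
    seed: int | None = None

    @property
    def median(self) -> pd.Series:
        return self.exposures.median()

    @property
    def iqr(self) -> pd.DataFrame:
        return self.exposures.quantile([0.25, 0.75])


def bootstrap_exposures(
    mutation_set,
    signatures: SignatureMatrix,
    n_iter: int = 200,
    sample_frac: float = 0.9,
    seed: int | None = None,
    *,
    replace: bool = False,
    discard_threshold: float = 0.06,
    tol: float = 1e-3,
) -> BootstrapResult:
    """Bootstrap the exposure fit by repeatedly subsampling the mutation set.

    Each iteration draws ``floor(sample_frac * n)`` mutations — without
    replacement by default (90% subsampling), or with replacement when
    ``replace=True`` — rebuilds the catalogue and re-fits exposures.
    Deterministic for a fixed seed.
    """
    if isinstance(mutation_set, MutationSet):
        channels = mutation_set.channels
    else:
        channels = np.asarray(mutation_set, dtype=np.int64)
    n = len(channels)
    if n < 10:
        raise ValueError(f"mutation set of size {n} is too small to subsample (need >= 10)")
    m = int(np.floor(sample_frac * n))
    if m < 1:
        raise ValueError("sample_frac too small: empty subsample")

    rng = np.random.default_rng(seed)
    rows = np.empty((n_iter, signatures.k))
    for i in range(n_iter):
        idx = rng.choice(n, size=m, replace=replace)
        cat = MutationCatalogue(np.bincount(channels[idx], minlength=N_CHANNELS))
        rows[i] = SignatureDeconvolution(cat, signatures, discard_threshold, tol)._fit_array()
    return BootstrapResult(pd.DataFrame(rows, columns=signatures.names), seed)


def compare_conditions(boot_a: BootstrapResult, boot_b: BootstrapResult) -> pd.DataFrame:
    """Compare bootstrap exposure distributions between two conditions.

    Per signature: a two-sided Mann-Whitney U test on the two bootstrap
    exposure vectors, a flag for disjoint interquartile ranges, and the
    effect direction.  A signature is *highlighted* only when p < 0.05 AND
    the IQRs do not overlap.
    """
    names_a = list(boot_a.exposures.columns)
    names_b = list(boot_b.exposures.columns)
    if names_a != names_b:
        raise ValueError(f"mismatched signature sets: {names_a} vs {names_b}")

    rows = []
    for name in names_a:
        x = boot_a.exposures[name].to_numpy()
        y = boot_b.exposures[name].to_numpy()
        if np.all(x == x[0]) and np.all(y == y[0]):
            # degenerate rank variance: identical constants are uninformative,
            # distinct constants are complete separation
            p = 1.0 if x[0] == y[0] else 0.0
        else:
            p = float(
                sps.mannwhitneyu(
                    x, y, alternative="two-sided", method="asymptotic", use_continuity=False
                ).pvalue
            )
        qa = np.quantile(x, [0.25, 0.75])
        qb = np.quantile(y, [0.25, 0.75])
        disjoint = bool(qa[1] < qb[0] or qb[1] < qa[0])
        med_a, med_b = float(np.median(x)), float(np.median(y))
        direction = "higher-in-B" if med_b > med_a else "higher-in-A" if med_a > med_b else "none"
        rows.append(
            {
                "signature": name,
                "median_a": med_a,
                "median_b": med_b,
                "p": p,
                "iqr_disjoint": disjoint,
                "highlighted": bool(p < 0.05 and disjoint),
                "direction": direction,
            }
        )
    return pd.DataFrame(rows)


def clonal_subclonal_comparison(
    cohort: Cohort,
    subtype: str,
    signatures: SignatureMatrix,
    n_iter: int = 200,
    sample_frac: float = 0.9,
    seed: int | None = None,
    *,
    min_set_size: int = 10,
) -> pd.DataFrame:
    """Bootstrap signature comparison of a subtype's clonal vs subclonal sets.

    Convenience wrapper chaining :func:`aggregate_clonal_subclonal`,
    :func:`bootstrap_exposures` on each set (condition A = clonal,
    condition B = subclonal) and :func:`compare_conditions`.
    """
    sets = aggregate_clonal_subclonal(cohort, subtype)
    if len(sets.clonal) < min_set_size or len(sets.subclonal) < min_set_size:
        raise ValueError(
            f"mutation sets too small for {subtype}: "
            f"{len(sets.clonal)} clonal / {len(sets.subclonal)} subclonal"
        )
    seed_b = None if seed is None else seed + 1
    boot_clonal = bootstrap_exposures(sets.clonal, signatures, n_iter, sample_frac, seed=seed)
    boot_subclonal = bootstrap_exposures(
        sets.subclonal, signatures, n_iter, sample_frac, seed=seed_b
    )
    return compare_conditions(boot_clonal, boot_subclonal)


# ---------------------------------------------------------------------------
# APOBEC consensus-site analysis
# ---------------------------------------------------------------------------

@dataclass
class ApobecDominanceResult:
    """Dominant vs subclonal proportions of mutations at APOBEC consensus sites."""

    gene: str
    subtype: str | None
    table: np.ndarray  # rows: dominant/subclonal; cols: APOBEC/other
    prop_dominant: float | None
    prop_subclonal: float | None
    p_value: float | None

    @property
    def empty(self) -> bool:
        return self.table.sum() == 0


def apobec_dominance_analysis(
    cohort: Cohort,
    gene: str,
    subtype: str | None = None,
    *,
    pathogenic_only: bool = True,
) -> ApobecDominanceResult:
    """Do a gene's subclonal mutations fall at APOBEC consensus sites more often?

    Builds the 2x2 table (dominant/subclonal) x (APOBEC consensus/other)
    over the gene's assessable SNVs and tests it with a two-sided Fisher's
    exact test.  Returns an empty result when no mutations are assessable.
    """
    from .clonality import annotate_clonality

    table = np.zeros((2, 2), dtype=np.int64)
    for profile in cohort:
        if subtype is not None and profile.subtype != subtype:
            continue
        for v, ann in zip(profile.variants, annotate_clonality(profile)):
            if v.gene != gene or ann.dominance == "not_assessable":
                continue
            if pathogenic_only and v.pathogenic != "pathogenic":
                continue
            if not (v.is_snv and v.context3 is not None):
                continue
            row = 0 if ann.dominance == "dominant" else 1
            col = 0 if is_apobec_site(v.ref_allele, v.alt_allele, v.context3) else 1
            table[row, col] += 1

    if table.sum() == 0:
        return ApobecDominanceResult(gene, subtype, table, None, None, None)
    n_dom, n_sub = table[0].sum(), table[1].sum()
    prop_dom = table[0, 0] / n_dom if n_dom else None
    prop_sub = table[1, 0] / n_sub if n_sub else None
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # zero margins legitimately give p = 1 here
        p = fisher_exact_2x2(table)
    return ApobecDominanceResult(gene, subtype, table, prop_dom, prop_sub, p)
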