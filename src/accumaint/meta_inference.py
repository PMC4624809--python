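"""Quantitative reverse-inference meta-analysis over a coordinate corpus.

Reverse inference asks: given that a brain location is active, how
probable is it that a study engages a given cognitive term? Over a corpus
of articles annotated with terms and MNI activation foci, the posterior
probability at a voxel is

    p(Term | Actv.) = p(Actv.|Term) p(Term) /
                      (p(Actv.|Term) p(Term) + p(Actv.|notTerm) (1 - p(Term)))

with the conditional activation probabilities estimated as activation
fractions among articles with and without the term. Association strength
is expressed as a signed posterior z from the Pearson chi-square of the
2x2 term-by-activation table. A contrast map is then interpreted by
finding its local maxima, averaging each term's posterior z over a small
spherical ROI around each peak (weighted by the contrast z), and ranking
terms by the evidence score = peak contrast z x ROI-averaged posterior z.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import ndimage

from ._porter import porter_stem
from .statmap import StatMap

__all__ = [
    "TermDatabase",
    "FociDatabase",
    "ActivationMasks",
    "build_term_db",
    "merge_foci",
    "activation_masks",
    "term_posterior_map",
    "term_posterior_z",
    "local_maxima",
    "roi_weighted_posterior_z",
    "evidence_scores",
    "top_terms",
    "load_stopwords",
    "DEFAULT_EXCLUDED_TERMS",
]

#: redundant or overly general terms dropped from the database
#: ("face*" is a prefix pattern)
DEFAULT_EXCLUDED_TERMS = ("face*", "house", "picture", "actor")

FociDatabase = dict  # article id -> list of [x, y, z] MNI mm coordinates


def load_stopwords() -> frozenset:
    text = resources.files("accumaint").joinpath("data/stopwords.txt").read_text()
    return frozenset(
        line.strip() for line in text.splitlines() if line.strip() and not line.startswith("#")
    )


_WORD_RE = re.compile(r"[a-z]+")


def _tokenize(text: str, stopwords: frozenset) -> list[str]:
    return [porter_stem(w) for w in _WORD_RE.findall(text.lower()) if w not in stopwords]


def _term_key(term: str, stopwords: frozenset) -> tuple[str, ...]:
    words = [w for w in _WORD_RE.findall(term.lower()) if w not in stopwords]
    return tuple(porter_stem(w) for w in words)


def _is_excluded(term: str, patterns) -> bool:
    t = term.lower().strip()
    for p in patterns:
        p = p.lower()
        if p.endswith("*"):
            if t.startswith(p[:-1]):
                return True
        elif t == p:
            return True
    return False


@dataclass
class TermDatabase:
    """Term annotations over an article corpus.

    articles maps article id -> set of retained terms; term_counts maps
    term -> number of annotated articles. Every retained term occurs in
    at least ``min_articles`` articles and none is on the excluded list.
    """

    articles: dict
    term_counts: dict = field(default_factory=dict)
    min_articles: int = 15

    def __post_init__(self):
        if not self.term_counts:
            counts: dict = {}
            for tset in self.articles.values():
                for t in tset:
                    counts[t] = counts.get(t, 0) + 1
            self.term_counts = counts

    @property
    def terms(self) -> list[str]:
        return sorted(self.term_counts)

    def with_term(self, term: str) -> list:
        if term not in self.term_counts:
            raise KeyError(f"term {term!r} not in database")
        return [a for a, tset in self.articles.items() if term in tset]

    def without_term(self, term: str) -> list:
        if term not in self.term_counts:
            raise KeyError(f"term {term!r} not in database")
        return [a for a, tset in self.articles.items() if term not in tset]

    @classmethod
    def from_annotations(
        cls, annotations: dict, min_articles: int = 1, excluded_terms=()
    ) -> "TermDatabase":
        """Build directly from explicit article -> term-set annotations
        (the synthetic-corpus path, where no text matching is needed)."""
        counts: dict = {}
        for tset in annotations.values():
            for t in tset:
                counts[t] = counts.get(t, 0) + 1
        keep = {
            t
            for t, n in counts.items()
            if n >= min_articles and not _is_excluded(t, excluded_terms)
        }
        articles = {a: {t for t in tset if t in keep} for a, tset in annotations.items()}
        return cls(articles, min_articles=min_articles)


def build_term_db(
    article_texts: dict,
    term_list,
    min_articles: int = 15,
    excluded_terms=DEFAULT_EXCLUDED_TERMS,
    stopwords: frozenset | None = None,
) -> TermDatabase:
    """Assign terms to articles by stemmed occurrence in title+abstract+keywords.

    Each article's concatenated text is lower-cased, stop-word-filtered
    and Porter-stemmed; a (one- or two-word) term is assigned iff its
    stemmed form occurs at least once (two-word terms must appear as
    consecutive non-stop-word tokens). Terms occurring in fewer than
    ``min_articles`` articles, and excluded terms, are dropped.
    """
    if not term_list:
        raise ValueError("term list must be non-empty")
    if not article_texts:
        raise ValueError("corpus must be non-empty")
    stopwords = load_stopwords() if stopwords is None else stopwords
    keys = {}
    for term in term_list:
        if _is_excluded(term, excluded_terms):
            continue
        key = _term_key(term, stopwords)
        if key:
            keys[term] = key
    annotations: dict = {}
    for art, text in article_texts.items():
        tokens = _tokenize(text, stopwords)
        token_set = set(tokens)
        bigrams = set(zip(tokens, tokens[1:]))
        found = set()
        for term, key in keys.items():
            if len(key) == 1 and key[0] in token_set:
                found.add(term)
            elif len(key) == 2 and key in bigrams:
                found.add(term)
        annotations[art] = found
    counts: dict = {}
    for tset in annotations.values():
        for t in tset:
            counts[t] = counts.get(t, 0) + 1
    keep = {t for t, n in counts.items() if n >= min_articles}
    articles = {a: {t for t in tset if t in keep} for a, tset in annotations.items()}
    return TermDatabase(articles, min_articles=min_articles)


def merge_foci(db_a: FociDatabase, db_b: FociDatabase) -> FociDatabase:
    """Union of two location databases keyed by article id.

    An id present in both keeps the union of its foci with exact
    duplicates stored once.
    """
    out: FociDatabase = {}
    for db in (db_a, db_b):
        for art, foci in db.items():
            bucket = out.setdefault(art, [])
            for f in foci:
                f = [float(c) for c in f]
                if f not in bucket:
                    bucket.append(f)
    return out


@dataclass
class ActivationMasks:
    """Per-article activated voxels on a fixed grid.

    A voxel counts as active for an article iff its center lies within
    ``radius_mm`` of any of the article's foci. Voxel sets are stored as
    flat indices into the grid.
    """

    grid: StatMap
    active: dict  # article id -> sorted unique flat voxel indices (np.ndarray)
    radius_mm: float

    def article_ids(self) -> list:
        return list(self.active)

    def activation_counts(self, article_ids) -> np.ndarray:
        """Number of listed articles active at each voxel (flat array)."""
        counts = np.zeros(int(np.prod(self.grid.shape)), dtype=np.int64)
        for a in article_ids:
            counts[self.active[a]] += 1
        return counts


def activation_masks(foci: FociDatabase, grid: StatMap, radius_mm: float = 10.0) -> ActivationMasks:
    """Rasterize each article's foci into a voxel activation set."""
    import warnings

    if radius_mm <= 0:
        raise ValueError("radius must be positive")
    shape = grid.shape
    active: dict = {}
    for art, points in foci.items():
        idx: list = []
        for p in points:
            vox = grid.sphere_indices(p, radius_mm)
            if vox.size == 0:
                inside = all(
                    grid.origin_mm[d] - radius_mm
                    <= p[d]
                    <= grid.origin_mm[d] + grid.spacing_mm[d] * (shape[d] - 1) + radius_mm
                    for d in range(3)
                )
                if not inside:
                    warnings.warn(f"focus {p} outside grid; ignored", stacklevel=2)
                continue
            idx.append(np.ravel_multi_index((vox[:, 0], vox[:, 1], vox[:, 2]), shape))
        active[art] = (
            np.unique(np.concatenate(idx)) if idx else np.empty(0, dtype=np.int64)
        )
    return ActivationMasks(grid=grid, active=active, radius_mm=radius_mm)


def _activation_fractions(term: str, termdb: TermDatabase, masks: ActivationMasks):
    with_ids = [a for a in termdb.with_term(term) if a in masks.active]
    without_ids = [a for a in termdb.without_term(term) if a in masks.active]
    n_with, n_without = len(with_ids), len(without_ids)
    cw = masks.activation_counts(with_ids)
    cwo = masks.activation_counts(without_ids)
    return cw, n_with, cwo, n_without


def term_posterior_map(
    term: str, termdb: TermDatabase, masks: ActivationMasks, prior: float = 0.5
) -> StatMap:
    """Voxelwise posterior probability p(Term | Activation).

    p(Actv.|Term) and p(Actv.|notTerm) are the activation fractions among
    articles with and without the term; Bayes' rule is applied with the
    supplied prior p(Term) (0.5 by default, weighing both classes
    equally regardless of term frequency). Voxels where no article is
    active have an undefined posterior, encoded as NaN.
    """
    if not 0.0 <= prior <= 1.0:
        raise ValueError("prior must be in [0,1]")
    cw, n_with, cwo, n_without = _activation_fractions(term, termdb, masks)
    if n_with == 0 or n_without == 0:
        raise ValueError(f"term {term!r} needs articles both with and without it")
    p_act_t = cw / n_with
    p_act_nt = cwo / n_without
    denom = p_act_t * prior + p_act_nt * (1.0 - prior)
    with np.errstate(invalid="ignore", divide="ignore"):
        post = np.where(denom > 0, p_act_t * prior / np.where(denom > 0, denom, 1.0), np.nan)
    return masks.grid.like(post.reshape(masks.grid.shape))


def term_posterior_z(term: str, termdb: TermDatabase, masks: ActivationMasks) -> StatMap:
    """Signed posterior z per voxel from the 2x2 term-by-activation table.

    Pearson chi-square (no continuity correction) on counts
    [[with&active, with&inactive], [without&active, without&inactive]],
    converted to |z| = sqrt(chi2) (1 df), signed positive iff the
    with-term activation fraction exceeds the without-term fraction.
    Degenerate margins (no active or no inactive articles at a voxel)
    yield NaN.
    """
    cw, n_with, cwo, n_without = _activation_fractions(term, termdb, masks)
    if n_with < 2 or n_without < 2:
        raise ValueError(f"term {term!r} needs >= 2 articles with and without it")
    a = cw.astype(float)
    b = n_with - a
    c = cwo.astype(float)
    d = n_without - c
    n = float(n_with + n_without)
    row1 = a + b
    row2 = c + d
    col1 = a + c
    col2 = b + d
    denom = row1 * row2 * col1 * col2
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = n * (a * d - b * c) ** 2 / denom
        z = np.sqrt(chi2)
        sign = np.where(a / n_with >= c / n_without, 1.0, -1.0)
        out = np.where(denom > 0, sign * z, np.nan)
    return masks.grid.like(out.reshape(masks.grid.shape))


@dataclass(frozen=True)
class Peak:
    ijk: tuple
    xyz_mm: tuple
    z: float
    cluster: int


def local_maxima(
    statmap: StatMap, z_thresh: float = 2.3, min_distance_mm: float = 30.0
) -> list[Peak]:
    """Local maxima of a thresholded map, with peak-to-peak suppression.

    Candidates are suprathreshold voxels that are 26-connected local
    maxima; they are accepted greedily in descending z, skipping any
    candidate within ``min_distance_mm`` of an already accepted peak.
    Clusters are 26-connected components above threshold.
    """
    data = np.nan_to_num(statmap.data, nan=-np.inf)
    above = data > z_thresh
    if not above.any():
        return []
    structure = np.ones((3, 3, 3), dtype=bool)
    labels, _ = ndimage.label(above, structure=structure)
    dil = ndimage.maximum_filter(data, footprint=structure, mode="constant", cval=-np.inf)
    is_max = above & (data >= dil)
    cand = np.argwhere(is_max)
    order = np.argsort(-data[tuple(cand.T)], kind="stable")
    cand = cand[order]
    spacing = np.asarray(statmap.spacing_mm)
    accepted: list[Peak] = []
    accepted_mm: list[np.ndarray] = []
    for ijk in cand:
        xyz = statmap.voxel_to_world(ijk)
        if any(np.linalg.norm(xyz - p) < min_distance_mm for p in accepted_mm):
            continue
        accepted_mm.append(xyz)
        accepted.append(
            Peak(
                ijk=tuple(int(i) for i in ijk),
                xyz_mm=tuple(float(v) for v in xyz),
                z=float(data[tuple(ijk)]),
                cluster=int(labels[tuple(ijk)]),
            )
        )
    return accepted


def roi_weighted_posterior_z(
    peak_xyz_mm,
    posterior_z_map: StatMap,
    contrast_map: StatMap,
    radius_mm: float = 5.0,
) -> float:
    """Contrast-weighted mean posterior z in a sphere around a peak.

    Weights are the contrast z-values inside the sphere, clamped to zero
    below (weights must form a convex combination) and normalized to unit
    sum; voxels with missing posterior z are dropped and the weights
    renormalized. If no voxel carries positive contrast weight, the mean
    is unweighted over the non-missing voxels.
    """
    vox = contrast_map.sphere_indices(peak_xyz_mm, radius_mm)
    if vox.shape[0] == 0:
        raise ValueError("sphere contains no voxels")
    idx = (vox[:, 0], vox[:, 1], vox[:, 2])
    post = posterior_z_map.data[idx]
    keep = ~np.isnan(post)
    if not keep.any():
        raise ValueError("all posterior z-values missing inside the sphere")
    post = post[keep]
    w = np.clip(contrast_map.data[idx][keep], 0.0, None)
    if w.sum() <= 0:
        w = np.ones_like(post)
    w = w / w.sum()
    return float(np.sum(w * post))


def evidence_scores(
    contrast: StatMap,
    termdb: TermDatabase,
    masks: ActivationMasks,
    contrast_id: str = "contrast",
    z_thresh: float = 2.3,
    min_distance_mm: float = 30.0,
    roi_radius_mm: float = 5.0,
    prior: float = 0.5,
) -> pd.DataFrame:
    """One evidence row per (peak, term) for a contrast map.

    evidence score = peak contrast z x ROI-average posterior z of the
    term around that peak. Returns the long table sorted by score.
    """
    peaks = local_maxima(contrast, z_thresh=z_thresh, min_distance_mm=min_distance_mm)
    if not peaks:
        raise ValueError("no suprathreshold peaks in the contrast map")
    rows = []
    for term in termdb.terms:
        try:
            zmap = term_posterior_z(term, termdb, masks)
        except ValueError:
            continue
        for pk in peaks:
            try:
                roi_z = roi_weighted_posterior_z(pk.xyz_mm, zmap, contrast, roi_radius_mm)
            except ValueError:
                continue
            rows.append(
                {
                    "contrast": contrast_id,
                    "peak_x": pk.xyz_mm[0],
                    "peak_y": pk.xyz_mm[1],
                    "peak_z": pk.xyz_mm[2],
                    "cluster": pk.cluster,
                    "term": term,
                    "peak_z_value": pk.z,
                    "roi_post_z": roi_z,
                    "evidence_score": pk.z * roi_z,
                }
            )
    return pd.DataFrame(rows).sort_values("evidence_score", ascending=False, ignore_index=True)


def top_terms(rows: pd.DataFrame, k: int = 8, per_cluster_k: int = 3) -> list[str]:
    """Highest-evidence terms for a contrast.

    A term associated with several peaks keeps only its highest-scoring
    row. Contrasts with a single cluster report the top ``per_cluster_k``
    terms per cluster; otherwise the top ``k`` overall.
    """
    if len(rows) == 0:
        raise ValueError("no evidence rows")
    best = rows.sort_values("evidence_score", ascending=False).drop_duplicates("term")
    n_clusters = rows["cluster"].nunique() if "cluster" in rows else 1
    limit = per_cluster_k if n_clusters == 1 else k
    return best.head(limit)["term"].tolist()
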