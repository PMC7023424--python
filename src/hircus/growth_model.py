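"""Bivariate repeatability-maternal animal model for growth traits.

Body weight (BW) is analysed jointly with one conformation trait (chest
girth, body length or height at withers):

    y_i = X_i b_i + Z_a a_i + Z_m m_i + Z_p p_i + Z_c c_i + e_i,  i = 1, 2

with a ~ N(0, A (x) G0) additive genetic effects over the pedigree, maternal
effects i.i.d. per dam, permanent environmental effects per recorded animal
(tying the repeated records together), common environmental effects per herd,
and record-level residuals; every term carries an unstructured 2x2 covariance
matrix.  Fixed effects are the full cross-classified cell means of age class
x sex x parity x birth type with empty cells dropped.

Estimation is Bayesian: partially collapsed Gibbs sampling with flat (or
optionally proper inverse-Wishart) priors on all covariance matrices — see
:mod:`hircus._samplers` and docs/methods.md for why the covariance partition
must be sampled from collapsed conditionals.  Records missing the second
trait are masked and conditionally imputed within the scan, never dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .pedigree import Pedigree, RelationshipMatrix
from .simulate import KidRecords

__all__ = [
    "ModelSpec",
    "PriorSpec",
    "DesignMatrices",
    "MCMCChain",
    "build_design",
    "gibbs_chain",
]

GROWTH_PARAM_NAMES = [
    "a11", "a12", "a22",
    "m11", "m12", "m22",
    "p11", "p12", "p22",
    "c11", "c12", "c22",
    "e11", "e12", "e22",
]

FIXED_FACTORS = ("age_class", "sex", "parity", "birth_type")


@dataclass
class ModelSpec:
    """Trait pair and term selection for one bivariate fit."""

    trait_pair: tuple[str, str] = ("bw", "cg")
    include_maternal: bool = True
    include_permanent_env: bool = True
    include_common_env: bool = True

    def __post_init__(self) -> None:
        if self.trait_pair[0] != "bw":
            raise ValueError("the first trait of the pair is always body weight")
        if self.trait_pair[1] not in ("cg", "bl", "hw"):
            raise ValueError("second trait must be one of cg, bl, hw")


@dataclass
class PriorSpec:
    """Inverse-Wishart prior per random term (scalar terms reduce to p = 1).

    The default is the flat (improper) prior on every covariance matrix,
    encoded as df = -(p + 1) with a zero scale, the conventional choice for
    animal-model Gibbs samplers: proper inverse-Wishart alternatives with a
    scale far below the data variance are not innocuous here, because the
    additive/maternal/permanent/common split is only weakly identified and a
    zero-attracting prior decides it.  A proper prior (df > p - 1, PSD
    scale) can be supplied per term; the posterior then uses the usual
    conjugate updates.
    """

    df: dict = field(
        default_factory=lambda: {
            "a": -3.0, "m": -3.0, "p": -3.0, "c": -3.0, "e": -3.0
        }
    )
    scale: dict = field(
        default_factory=lambda: {
            k: np.zeros((2, 2)) for k in ("a", "m", "p", "c", "e")
        }
    )

    def __post_init__(self) -> None:
        for term, S in self.scale.items():
            S = np.atleast_2d(np.asarray(S, dtype=float))
            self.scale[term] = S
            dim = S.shape[0]
            if np.linalg.eigvalsh(S).min() < -1e-10:
                raise ValueError(f"prior scale for term {term!r} not PSD")
            flat = not S.any()
            if not flat and self.df[term] <= dim - 1:
                raise ValueError(
                    f"proper prior for term {term!r} needs df > dim - 1"
                )

    def arrays_2d(self) -> tuple[np.ndarray, np.ndarray]:
        """(df (5,), scale (5,3)) in term order a, m, p, c, e for the kernel."""
        order = ("a", "m", "p", "c", "e")
        df = np.array([float(self.df[t]) for t in order])
        s = np.zeros((5, 3))
        for i, t in enumerate(order):
            S = self.scale[t]
            if S.shape[0] == 1:
                S = S[0, 0] * np.eye(2)
            s[i] = (S[0, 0], S[0, 1], S[1, 1])
        return df, s

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PriorSpec":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        df = {k: float(v) for k, v in raw.get("df", {}).items()}
        scale = {k: np.asarray(v, dtype=float) for k, v in raw.get("scale", {}).items()}
        base = cls()
        base.df.update(df)
        for k, v in scale.items():
            base.scale[k] = np.atleast_2d(v)
        return cls(df=base.df, scale=base.scale)


def _csr_lists(codes: np.ndarray, n_levels: int) -> tuple[np.ndarray, np.ndarray]:
    """Group record positions by level code: (ptr (n_levels+1,), idx)."""
    order = np.argsort(codes, kind="stable")
    counts = np.bincount(codes, minlength=n_levels)
    ptr = np.zeros(n_levels + 1, dtype=np.int64)
    np.cumsum(counts, out=ptr[1:])
    return ptr, order.astype(np.int64)


def _incidence(codes: np.ndarray, n_levels: int) -> sp.csr_matrix:
    n = len(codes)
    return sp.csr_matrix(
        (np.ones(n), (np.arange(n), codes)), shape=(n, n_levels)
    )


@dataclass
class DesignMatrices:
    """Aligned observation vectors, incidence matrices and index arrays.

    ``miss`` codes per record row: 0 both traits observed, 1 second trait
    missing, 2 body weight missing.  The sparse incidences (one row per
    record, one column per level) describe a single trait; the bivariate
    system block-diagonalises them internally.
    """

    y1: np.ndarray
    y2: np.ndarray
    miss: np.ndarray
    X: sp.csr_matrix
    Z_a: sp.csr_matrix
    Z_m: sp.csr_matrix
    Z_p: sp.csr_matrix
    Z_c: sp.csr_matrix
    cell_codes: np.ndarray
    anim_codes: np.ndarray
    dam_codes: np.ndarray
    pe_codes: np.ndarray
    herd_codes: np.ndarray
    parent_pos: np.ndarray      # (n_animals, 2) pedigree sire/dam positions
    cell_labels: list
    animal_ids: list
    dam_labels: list
    pe_labels: list
    herd_labels: list
    trait_pair: tuple[str, str]
    spec: ModelSpec

    @property
    def n_records(self) -> int:
        return len(self.y1)

    @property
    def y(self) -> np.ndarray:
        """Stacked bivariate observation vector (trait 1 block then trait 2)."""
        return np.concatenate([self.y1, self.y2])


def build_design(
    records: KidRecords, ped: Pedigree, spec: ModelSpec | None = None
) -> DesignMatrices:
    """Assemble design structures for one trait pair from a records table.

    One row pair per measured kid x age class.  Fixed effects are coded as
    full-interaction cells over age class, sex, parity and birth type; only
    observed cells get a column.  Rows with the second trait missing are kept
    and masked; rows missing both traits are dropped.
    """
    spec = spec or ModelSpec()
    t2 = spec.trait_pair[1]
    meas = records.measures.merge(
        records.kids[["kid", "dam", "sex", "birth_type", "parity", "herd"]],
        on="kid",
        how="left",
    )
    if len(meas) == 0:
        raise ValueError("no measurement records to analyse")
    missing_kids = sorted(set(meas.loc[meas["dam"].isna(), "kid"]))
    if missing_kids:
        raise ValueError(f"records reference unknown kids: {missing_kids[:5]}")
    absent = [k for k in meas["kid"].unique() if k not in ped.index]
    if absent:
        raise ValueError(f"record animals absent from pedigree: {absent[:5]}")

    y1 = meas["bw"].to_numpy(dtype=float)
    y2 = meas[t2].to_numpy(dtype=float)
    miss = np.zeros(len(meas), dtype=np.int64)
    miss[np.isnan(y2)] = 1
    miss[np.isnan(y1)] = 2
    keep = ~(np.isnan(y1) & np.isnan(y2))
    meas, y1, y2, miss = meas[keep], y1[keep], y2[keep], miss[keep]
    if len(meas) == 0:
        raise ValueError("no measurement records to analyse")
    y1 = np.nan_to_num(y1)
    y2 = np.nan_to_num(y2)

    cell_key = meas[list(FIXED_FACTORS)].astype(str).agg(":".join, axis=1)
    cell_labels = sorted(cell_key.unique())
    cell_codes = cell_key.map({c: i for i, c in enumerate(cell_labels)}).to_numpy()

    anim_codes = meas["kid"].map(ped.index).to_numpy(dtype=np.int64)
    dam_labels = sorted(meas["dam"].unique())
    dam_codes = meas["dam"].map({d: i for i, d in enumerate(dam_labels)}).to_numpy()
    pe_labels = sorted(meas["kid"].unique())
    pe_codes = meas["kid"].map({k: i for i, k in enumerate(pe_labels)}).to_numpy()
    herd_labels = sorted(meas["herd"].unique())
    herd_codes = meas["herd"].map({h: i for i, h in enumerate(herd_labels)}).to_numpy()

    return DesignMatrices(
        y1=y1, y2=y2, miss=miss,
        X=_incidence(cell_codes, len(cell_labels)),
        Z_a=_incidence(anim_codes, len(ped)),
        Z_m=_incidence(dam_codes, len(dam_labels)),
        Z_p=_incidence(pe_codes, len(pe_labels)),
        Z_c=_incidence(herd_codes, len(herd_labels)),
        cell_codes=cell_codes.astype(np.int64),
        anim_codes=anim_codes,
        parent_pos=ped.parent_indices(),
        dam_codes=dam_codes.astype(np.int64),
        pe_codes=pe_codes.astype(np.int64),
        herd_codes=herd_codes.astype(np.int64),
        cell_labels=cell_labels,
        animal_ids=ped.ids,
        dam_labels=dam_labels,
        pe_labels=pe_labels,
        herd_labels=herd_labels,
        trait_pair=spec.trait_pair,
        spec=spec,
    )


@dataclass
class MCMCChain:
    """Retained post-burn-in, thinned samples plus run metadata."""

    samples: pd.DataFrame
    meta: dict

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def kind(self) -> str:
        return self.meta.get("kind", "growth")

    def write(self, path: str | Path, *, sep: str = "\t") -> None:
        """Samples table plus a JSON metadata sidecar next to it."""
        path = Path(path)
        self.samples.to_csv(path, sep=sep, index=False)
        meta = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in self.meta.items()
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=2, default=str)
        )

    @classmethod
    def read(cls, path: str | Path, *, sep: str = "\t") -> "MCMCChain":
        path = Path(path)
        samples = pd.read_csv(path, sep=sep)
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(samples, meta)


def gibbs_chain(
    design: DesignMatrices,
    A: RelationshipMatrix,
    priors: PriorSpec | None = None,
    n_iter: int = 100_000,
    burn_in: int = 10_000,
    thin: int = 10,
    seed: int = 0,
    mh_steps: int = 8,
    mh_scale: float | None = None,
    collapse: str = "auto",
) -> MCMCChain:
    """Run the Gibbs sampler for a built design and relationship matrix.

    Chain defaults mirror the full estimation protocol (100,000 iterations,
    10,000 burn-in, thinning 10); scale them down for experiments.
    Deterministic given the seed.
    """
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    if A.order != design.animal_ids:
        raise ValueError("relationship matrix order does not match the design")
    priors = priors or PriorSpec()
    pdf, ps = priors.arrays_2d()

    from ._samplers import growth_gibbs_block_kernel, growth_gibbs_kernel

    q = len(design.animal_ids)
    cell_ptr, cell_idx = _csr_lists(design.cell_codes, len(design.cell_labels))
    anim_ptr, anim_idx = _csr_lists(design.anim_codes, q)
    dam_ptr, dam_idx = _csr_lists(design.dam_codes, len(design.dam_labels))
    herd_ptr, herd_idx = _csr_lists(design.herd_codes, len(design.herd_labels))

    spec = design.spec

    # closed two-generation herd check: recorded kids with unrecorded founder
    # parents, and kids/sires/dams each confined to a single herd, enable the
    # herd-block collapsed covariance update
    par = design.parent_pos
    nrec = np.diff(anim_ptr)
    recorded = nrec > 0
    rec_idx = np.where(recorded)[0]
    sire_of = par[:, 0].astype(np.int64)
    dam_of = par[:, 1].astype(np.int64)
    dam_level_of = np.full(q, -1, dtype=np.int64)
    dam_level_of[design.anim_codes] = design.dam_codes
    index = {aid: i for i, aid in enumerate(design.animal_ids)}
    dam_anim = np.array(
        [index.get(d, -1) for d in design.dam_labels], dtype=np.int64
    )
    block_ok = bool(
        spec.include_maternal
        and spec.include_permanent_env
        and spec.include_common_env
        and collapse in ("auto", "block")
        and len(rec_idx) > 0
        and (sire_of[rec_idx] >= 0).all()
        and (dam_of[rec_idx] >= 0).all()
        and (dam_anim >= 0).all()
        and (dam_of[rec_idx] == dam_anim[dam_level_of[rec_idx]]).all()
    )
    if block_ok:
        parents = np.unique(np.concatenate([sire_of[rec_idx], dam_of[rec_idx]]))
        block_ok = bool(
            (par[parents] < 0).all()          # parents are founders
            and (~recorded[parents]).all()    # parents carry no records
            and not np.isin(rec_idx, np.concatenate(
                [par[:, 0], par[:, 1]])).any()  # recorded kids are terminal
        )
    herd_level_of = np.full(q, -1, dtype=np.int64)
    herd_level_of[design.anim_codes] = design.herd_codes
    sire_anim = np.zeros(0, dtype=np.int64)
    sire_level_of = np.full(q, -1, dtype=np.int64)
    herd_of_sire = np.zeros(0, dtype=np.int64)
    herd_of_dam = np.zeros(0, dtype=np.int64)
    if block_ok:
        # closed-herd checks: each kid, sire and dam maps to a single herd
        kid_herds = pd.DataFrame(
            {"k": design.anim_codes, "h": design.herd_codes}
        ).groupby("k")["h"].nunique()
        block_ok = bool((kid_herds == 1).all())
    if block_ok:
        sire_anim = np.unique(sire_of[rec_idx])
        sire_level_of[sire_anim] = np.arange(len(sire_anim))
        herd_of_sire = np.full(len(sire_anim), -1, dtype=np.int64)
        herd_of_dam = np.full(len(dam_anim), -1, dtype=np.int64)
        for k in rec_idx:
            s = sire_level_of[sire_of[k]]
            d = dam_level_of[k]
            h = herd_level_of[k]
            if herd_of_sire[s] == -1:
                herd_of_sire[s] = h
            elif herd_of_sire[s] != h:
                block_ok = False
            if herd_of_dam[d] == -1:
                herd_of_dam[d] = h
            elif herd_of_dam[d] != h:
                block_ok = False

    if block_ok:
        nherd = len(design.herd_labels)
        fam_ptr, fam_idx = _csr_lists(
            dam_level_of[rec_idx], len(design.dam_labels)
        )
        fam_idx = rec_idx[fam_idx]
        hs_ptr, hs_idx = _csr_lists(herd_of_sire, nherd)
        hd_ptr, hd_idx = _csr_lists(herd_of_dam, nherd)
        maxdim = 2 * (1 + int(np.max(np.diff(hs_ptr))))
        maxfam = int(np.max(np.diff(fam_ptr))) + 1
        is_sire = np.zeros(q, dtype=np.bool_)
        is_sire[sire_anim] = True
        is_dam = np.zeros(q, dtype=np.bool_)
        is_dam[dam_anim] = True
        kid_sire_level = np.full(q, -1, dtype=np.int64)
        kid_sire_level[rec_idx] = sire_level_of[sire_of[rec_idx]]
        if mh_scale is None:
            mh_scale = max(0.04, 1.2 / np.sqrt(len(rec_idx)))
        raw = growth_gibbs_block_kernel(
            np.ascontiguousarray(design.y1, dtype=np.float64),
            np.ascontiguousarray(design.y2, dtype=np.float64),
            np.ascontiguousarray(design.miss, dtype=np.int64),
            design.cell_codes, herd_level_of,
            cell_ptr, cell_idx, anim_ptr, anim_idx,
            kid_sire_level, dam_level_of,
            sire_anim, dam_anim,
            fam_ptr, fam_idx, hs_ptr, hs_idx, hd_ptr, hd_idx,
            sire_of, dam_of,
            is_sire, is_dam,
            pdf, ps,
            int(n_iter), int(burn_in), int(thin), int(seed),
            int(mh_steps * 2), float(mh_scale), int(maxdim), int(maxfam),
        )
    else:
        lam, Q = np.linalg.eigh(A.values)
        lam = np.clip(lam, 0.0, None)
        Q = np.ascontiguousarray(Q)
        Ainv = np.ascontiguousarray(A.inverse())
        if mh_scale is None:
            mh_scale = max(0.03, 1.5 / np.sqrt(q))
        raw = growth_gibbs_kernel(
            np.ascontiguousarray(design.y1, dtype=np.float64),
            np.ascontiguousarray(design.y2, dtype=np.float64),
            np.ascontiguousarray(design.miss, dtype=np.int64),
            design.cell_codes, design.anim_codes, design.dam_codes,
            design.herd_codes,
            cell_ptr, cell_idx, anim_ptr, anim_idx, dam_ptr, dam_idx,
            herd_ptr, herd_idx,
            Ainv, Q, lam,
            spec.include_maternal, spec.include_permanent_env,
            spec.include_common_env,
            pdf, ps,
            int(n_iter), int(burn_in), int(thin), int(seed),
            int(mh_steps), float(mh_scale),
        )
    samples = pd.DataFrame(raw, columns=GROWTH_PARAM_NAMES)
    meta = {
        "kind": "growth",
        "trait_pair": list(design.trait_pair),
        "n_iter": int(n_iter),
        "burn_in": int(burn_in),
        "thin": int(thin),
        "seed": int(seed),
        "n_records": int(design.n_records),
        "n_animals": q,
        "n_dams": len(design.dam_labels),
        "n_pe": len(design.pe_labels),
        "n_herds": len(design.herd_labels),
        "n_cells": len(design.cell_labels),
        "herd_block_collapsed": block_ok,
        "include_maternal": spec.include_maternal,
        "include_permanent_env": spec.include_permanent_env,
        "include_common_env": spec.include_common_env,
        "prior_df": {k: float(v) for k, v in priors.df.items()},
        "prior_scale": {k: v.tolist() for k, v in priors.scale.items()},
    }
    return MCMCChain(samples, meta)
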