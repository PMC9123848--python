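"""Modular reduction, control-reference z-scoring and summary features.

The ROI-level connectivity matrix is reduced to module level (block
averages, including an averaged within-module entry on the diagonal),
vectorized over the M(M+1)/2 unordered module pairs, and z-scored
connection-wise against a healthy-control reference.  Summary features
are then taken at three spatial scales:

* global   -- mean and SD of all connection z-scores;
* hemispheric -- mean z over connections with both endpoints in the
  lead-bearing hemisphere(s), averaged across hemispheres when bilateral;
* lobar    -- mean z over connections within the lead-bearing lobe(s)
  (lobe regions are hemisphere-specific), averaged across lobes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import ConnectivityRecord
from .parcellation import Parcellation

#: a subject's module-level connectivity, keyed by band name
SubjectConnectivity = dict[str, ConnectivityRecord]


# ---------------------------------------------------------------------------
# reduction and vectorization

def reduce_to_modules(
    roi_record: ConnectivityRecord, parcellation: Parcellation
) -> ConnectivityRecord:
    """Average ROI-level imaginary coherence into module blocks.

    Off-diagonal entry (A, B) is the mean over all ROI pairs (i in A,
    j in B); the diagonal entry (A, A) is the mean over unordered ROI
    pairs within A.  Singleton modules have no within-module pair; their
    diagonal is left NaN with a warning and is later excluded from the
    connection vector.
    """
    if roi_record.level != "roi":
        raise ValueError("reduce_to_modules expects an ROI-level record")
    rows = parcellation.module_rows(roi_record.ids)
    for roi in roi_record.ids:
        parcellation.module_of(roi)  # raises naming any unmapped ROI
    mods = parcellation.module_ids
    vals = roi_record.values
    out = np.full((len(mods), len(mods)), np.nan)
    for a, ma in enumerate(mods):
        ia = rows[ma]
        for b in range(a, len(mods)):
            ib = rows[mods[b]]
            if a == b:
                if len(ia) < 2:
                    warnings.warn(
                        f"module {ma} has a single ROI; its within-module "
                        "connectivity is undefined and will be excluded",
                        stacklevel=2,
                    )
                    continue
                block = vals[np.ix_(ia, ia)]
                out[a, a] = block[np.triu_indices(len(ia), k=1)].mean()
            else:
                out[a, b] = out[b, a] = vals[np.ix_(ia, ib)].mean()
    return ConnectivityRecord(
        subject_id=roi_record.subject_id,
        band=roi_record.band,
        level="module",
        ids=list(mods),
        values=out,
    )


def vectorize_connections(
    module_record: ConnectivityRecord,
) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Upper triangle (diagonal included) as an ordered connection vector.

    Pairs are ordered (i, j) with i <= j in ascending module id; NaN
    diagonal entries of singleton modules are excluded.  For M modules
    without singletons the vector has length M(M+1)/2.
    """
    if module_record.level != "module":
        raise ValueError("vectorize_connections expects a module-level record")
    mods = module_record.ids
    pairs: list[tuple[int, int]] = []
    vals: list[float] = []
    for a in range(len(mods)):
        for b in range(a, len(mods)):
            v = module_record.values[a, b]
            if a == b and np.isnan(v):
                continue  # singleton module: no within-module entry
            pairs.append((mods[a], mods[b]))
            vals.append(v)
    return pairs, np.asarray(vals, dtype=float)


# ---------------------------------------------------------------------------
# control reference and z-scores

@dataclass
class ControlReference:
    """Per-connection, per-band mean and SD across the control cohort."""

    pairs: list[tuple[int, int]]
    mean: dict[str, np.ndarray]
    sd: dict[str, np.ndarray]
    n_controls: int

    @property
    def bands(self) -> list[str]:
        return list(self.mean)


@dataclass
class NormalizedFC:
    """A subject's connection z-scores against the control reference."""

    subject_id: str
    pairs: list[tuple[int, int]]
    z: dict[str, np.ndarray] = field(repr=False)

    @property
    def bands(self) -> list[str]:
        return list(self.z)


def build_control_reference(
    controls: Sequence[SubjectConnectivity],
) -> ControlReference:
    """Connection-wise sample mean and SD (n-1 denominator) over controls."""
    if len(controls) < 2:
        raise ValueError("a control reference needs at least 2 control subjects")
    bands = list(controls[0])
    ref_pairs = None
    mean: dict[str, np.ndarray] = {}
    sd: dict[str, np.ndarray] = {}
    for band in bands:
        mat = []
        for subj in controls:
            pairs, vec = vectorize_connections(subj[band])
            if ref_pairs is None:
                ref_pairs = pairs
            elif pairs != ref_pairs:
                raise ValueError("controls use inconsistent parcellations")
            mat.append(vec)
        arr = np.vstack(mat)
        mean[band] = arr.mean(axis=0)
        sd[band] = arr.std(axis=0, ddof=1)
        if np.any(sd[band] == 0):
            k = int(np.flatnonzero(sd[band] == 0)[0])
            raise ValueError(
                f"degenerate control reference: zero SD at connection "
                f"{ref_pairs[k]} in band {band!r}"
            )
    return ControlReference(pairs=ref_pairs, mean=mean, sd=sd, n_controls=len(controls))


def zscore_subject(
    subject: SubjectConnectivity, reference: ControlReference
) -> NormalizedFC:
    """z = (value - control mean) / control SD, per connection and band."""
    z: dict[str, np.ndarray] = {}
    subject_id = None
    for band, record in subject.items():
        if band not in reference.mean:
            raise KeyError(f"band {band!r} is missing from the control reference")
        pairs, vec = vectorize_connections(record)
        if pairs != reference.pairs:
            raise ValueError("subject parcellation does not match the reference")
        z[band] = (vec - reference.mean[band]) / reference.sd[band]
        subject_id = record.subject_id
    return NormalizedFC(subject_id=subject_id, pairs=list(reference.pairs), z=z)


# ---------------------------------------------------------------------------
# summary features

def global_features(nfc: NormalizedFC) -> dict[str, tuple[float, float]]:
    """Per band: (mean, sample SD) of the connection z-score vector."""
    out = {}
    for band, z in nfc.z.items():
        out[band] = (float(z.mean()), float(z.std(ddof=1)) if z.size > 1 else 0.0)
    return out


def _pair_mask(
    pairs: list[tuple[int, int]],
    members: set[int],
    mode: str,
) -> np.ndarray:
    if mode == "both_endpoint":
        keep = [(i in members) and (j in members) for i, j in pairs]
    elif mode == "any_endpoint":
        keep = [(i in members) or (j in members) for i, j in pairs]
    else:
        raise ValueError(f"mode must be 'both_endpoint' or 'any_endpoint', got {mode!r}")
    return np.asarray(keep, dtype=bool)


def hemispheric_feature(
    nfc: NormalizedFC,
    lead_hemispheres: Sequence[str],
    parcellation: Parcellation,
    mode: str = "both_endpoint",
) -> dict[str, float]:
    """Mean z within the lead-bearing hemisphere(s), per band.

    By default a connection counts as "within" a hemisphere when both
    endpoint modules lie in it; bilateral leads average the two
    per-hemisphere means.
    """
    hemis = sorted(set(lead_hemispheres))
    if not hemis:
        raise ValueError("lead_hemispheres must be nonempty")
    if not set(hemis) <= {"L", "R"}:
        raise ValueError(f"lead hemispheres must be within {{L, R}}, got {hemis}")
    out: dict[str, float] = {}
    for band, z in nfc.z.items():
        per_h = []
        for h in hemis:
            members = set(parcellation.modules_in(hemisphere=h))
            mask = _pair_mask(nfc.pairs, members, mode)
            if not mask.any():
                raise ValueError(f"no qualifying connections in hemisphere {h!r}")
            per_h.append(z[mask].mean())
        out[band] = float(np.mean(per_h))
    return out


def lobar_feature(
    nfc: NormalizedFC,
    lead_lobes: Sequence[str],
    parcellation: Parcellation,
    lead_hemispheres: Sequence[str] | None = None,
    mode: str = "both_endpoint",
) -> dict[str, float]:
    """Mean z within the lead-bearing lobe(s), per band.

    Lobe regions are hemisphere-specific (e.g. left frontal); the regions
    considered are each lead lobe crossed with the lead hemispheres (both
    hemispheres when unspecified).  Multiple regions are averaged.
    """
    lobes = list(dict.fromkeys(lead_lobes))
    if not lobes:
        raise ValueError("lead_lobes must be nonempty")
    unknown = set(lobes) - set(parcellation.lobes)
    if unknown:
        raise ValueError(f"lobes not present in the parcellation: {sorted(unknown)}")
    hemis = sorted(set(lead_hemispheres)) if lead_hemispheres else ["L", "R"]
    regions = []
    for lobe in lobes:
        for h in hemis:
            members = set(parcellation.modules_in(lobe=lobe, hemisphere=h))
            if members:
                regions.append((lobe, h, members))
    if not regions:
        raise ValueError(f"no modules found for lobes {lobes} in hemispheres {hemis}")
    out: dict[str, float] = {}
    for band, z in nfc.z.items():
        per_region = []
        for lobe, h, members in regions:
            mask = _pair_mask(nfc.pairs, members, mode)
            if not mask.any():
                raise ValueError(
                    f"lobe {lobe!r} ({h}) has no qualifying connection"
                )
            per_region.append(z[mask].mean())
        out[band] = float(np.mean(per_region))
    return out


def feature_table(
    nfcs: Sequence[NormalizedFC],
    leads: Mapping[str, tuple[Sequence[str], Sequence[str]]],
    parcellation: Parcellation,
    hemispheric_mode: str = "both_endpoint",
) -> pd.DataFrame:
    """Long-form per-subject, per-band feature table.

    ``leads`` maps subject_id -> (lead_hemispheres, lead_lobes); subjects
    absent from it (controls) get NaN regional features.
    """
    rows = []
    for nfc in nfcs:
        glob = global_features(nfc)
        hemi = lob = None
        if nfc.subject_id in leads:
            lead_h, lead_l = leads[nfc.subject_id]
            hemi = hemispheric_feature(nfc, lead_h, parcellation, hemispheric_mode)
            lob = lobar_feature(nfc, lead_l, parcellation, lead_h, hemispheric_mode)
        for band, (gmean, gsd) in glob.items():
            rows.append(
                {
                    "subject_id": nfc.subject_id,
                    "band": band,
                    "global_mean": gmean,
                    "global_sd": gsd,
                    "hemispheric_mean": hemi[band] if hemi else np.nan,
                    "lobar_mean": lob[band] if lob else np.nan,
                }
            )
    return pd.DataFrame(rows)
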