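import numpy as np
import pandas as pd
import pytest

from rnsfc.containers import ConnectivityRecord
from rnsfc.features import (
    NormalizedFC,
    build_control_reference,
    feature_table,
    global_features,
    hemispheric_feature,
    lobar_feature,
    reduce_to_modules,
    vectorize_connections,
    zscore_subject,
)
from rnsfc.parcellation import make_parcellation


def _roi_record(values, parc, band="alpha", subject="s0"):
    vals = np.asarray(values, float)
    np.fill_diagonal(vals, np.nan)
    return ConnectivityRecord(subject, band, "roi", parc.roi_ids, vals)


def _module_record(parc, vec_by_pair, band="alpha", subject="s0"):
    """Build a module-level record from a {(i, j): value} mapping."""
    mods = parc.module_ids
    mat = np.zeros((len(mods), len(mods)))
    for (i, j), v in vec_by_pair.items():
        a, b = mods.index(i), mods.index(j)
        mat[a, b] = mat[b, a] = v
    return ConnectivityRecord(subject, band, "module", list(mods), mat)


def _nfc(parc, z_by_pair, band="alpha", subject="s0"):
    pairs = [(i, j) for a, i in enumerate(parc.module_ids)
             for j in parc.module_ids[a:]]
    z = np.array([z_by_pair.get(p, 0.0) for p in pairs])
    return NormalizedFC(subject, pairs, {band: z})


# ---------------------------------------------------------------------------
# reduction

def test_constant_roi_matrix_reduces_to_constant_modules(parc_tiny):
    rec = _roi_record(np.full((8, 8), 0.3), parc_tiny)
    mod = reduce_to_modules(rec, parc_tiny)
    assert np.allclose(mod.values, 0.3)


def test_cross_block_average_is_the_hand_mean():
    parc = make_parcellation(4, 2)
    vals = np.full((4, 4), np.nan)
    # module 0 = rois {0,1}, module 1 = rois {2,3}
    vals[0, 2], vals[0, 3], vals[1, 2], vals[1, 3] = 0.2, 0.4, 0.6, 0.8
    vals[2, 0], vals[3, 0], vals[2, 1], vals[3, 1] = 0.2, 0.4, 0.6, 0.8
    vals[0, 1] = vals[1, 0] = 0.1
    vals[2, 3] = vals[3, 2] = 0.9
    rec = _roi_record(vals, parc)
    mod = reduce_to_modules(rec, parc)
    assert mod.values[0, 1] == pytest.approx(0.5)  # mean of the 4 cross pairs
    assert mod.values[0, 0] == pytest.approx(0.1)  # single within pair
    assert mod.values[1, 1] == pytest.approx(0.9)


def test_default_44_module_reduction_yields_990_connections():
    parc = make_parcellation(218, 44)
    rng = np.random.default_rng(0)
    raw = rng.uniform(0, 1, (218, 218))
    rec = _roi_record((raw + raw.T) / 2, parc)
    pairs, vec = vectorize_connections(reduce_to_modules(rec, parc))
    assert len(vec) == 990


def test_singleton_module_diagonal_is_excluded_with_warning():
    parc = make_parcellation(3, 2)  # module sizes 2 and 1
    raw = np.full((3, 3), 0.4)
    with pytest.warns(UserWarning, match="single ROI"):
        mod = reduce_to_modules(_roi_record(raw, parc), parc)
    pairs, vec = vectorize_connections(mod)
    assert len(vec) == 2  # (0,0), (0,1); singleton (1,1) dropped


def test_reduce_rejects_unmapped_roi(parc_tiny):
    rec = ConnectivityRecord(
        "s0", "alpha", "roi", ["ghost"] + parc_tiny.roi_ids[1:],
        np.zeros((8, 8)),
    )
    with pytest.raises(KeyError, match="ghost"):
        reduce_to_modules(rec, parc_tiny)


def test_reduce_is_bounded_by_input_block_extremes(parc_tiny):
    rng = np.random.default_rng(1)
    raw = rng.uniform(0.1, 0.9, (8, 8))
    raw = (raw + raw.T) / 2
    mod = reduce_to_modules(_roi_record(raw.copy(), parc_tiny), parc_tiny)
    off = ~np.eye(8, dtype=bool)
    assert np.nanmin(mod.values) >= raw[off].min() - 1e-12
    assert np.nanmax(mod.values) <= raw[off].max() + 1e-12


@pytest.mark.parametrize("n_modules, expected", [(2, 3), (1, 1), (44, 990)])
def test_connection_vector_length_law(n_modules, expected):
    parc = make_parcellation(2 * n_modules, n_modules)
    mat = np.full((n_modules, n_modules), 0.2)
    rec = ConnectivityRecord("s", "beta", "module", parc.module_ids, mat)
    pairs, vec = vectorize_connections(rec)
    assert len(vec) == expected == n_modules * (n_modules + 1) // 2


# ---------------------------------------------------------------------------
# control reference and z-scoring

def test_reference_mean_and_sd_match_hand_computation(parc_tiny):
    recs = [
        {"alpha": _module_record(parc_tiny, {}, subject="c0")},
        {"alpha": _module_record(parc_tiny, {}, subject="c1")},
    ]
    recs[0]["alpha"].values[0, 1] = recs[0]["alpha"].values[1, 0] = 0.2
    recs[1]["alpha"].values[0, 1] = recs[1]["alpha"].values[1, 0] = 0.4
    # perturb the remaining connections so no SD degenerates to 0
    rng = np.random.default_rng(2)
    for k, r in enumerate(recs):
        v = r["alpha"].values
        jitter = rng.uniform(0.01, 0.05, v.shape)
        mask = np.ones_like(v, bool)
        mask[0, 1] = mask[1, 0] = False
        v[mask] += (jitter + jitter.T)[mask] * (1 if k else -1)
        r["alpha"].values[:] = (v + v.T) / 2
    ref = build_control_reference(recs)
    k = ref.pairs.index((0, 1))
    assert ref.mean["alpha"][k] == pytest.approx(0.3)
    assert ref.sd["alpha"][k] == pytest.approx(np.std([0.2, 0.4], ddof=1))
    assert ref.sd["alpha"][k] == pytest.approx(0.1414, abs=1e-4)
    assert ref.n_controls == 2


def test_identical_controls_give_degenerate_reference_error(parc_tiny):
    rec = {"alpha": _module_record(parc_tiny, {(0, 1): 0.5})}
    with pytest.raises(ValueError, match="zero SD"):
        build_control_reference([rec, rec])


def test_zscore_of_the_reference_mean_is_zero(parc_tiny):
    rng = np.random.default_rng(3)
    recs = []
    for s in range(3):
        m = rng.uniform(0.2, 0.8, (4, 4))
        m = (m + m.T) / 2
        recs.append({"alpha": ConnectivityRecord(
            f"c{s}", "alpha", "module", parc_tiny.module_ids, m)})
    ref = build_control_reference(recs)
    mean_rec = {"alpha": ConnectivityRecord(
        "mean", "alpha", "module", parc_tiny.module_ids,
        sum(r["alpha"].values for r in recs) / 3)}
    nfc = zscore_subject(mean_rec, ref)
    assert np.allclose(nfc.z["alpha"], 0.0, atol=1e-12)
    # one reference SD above the mean maps to z = 1
    up = {"alpha": ConnectivityRecord(
        "up", "alpha", "module", parc_tiny.module_ids,
        mean_rec["alpha"].values
        + _sym_from_vec(ref.sd["alpha"], parc_tiny))}
    assert np.allclose(zscore_subject(up, ref).z["alpha"], 1.0, atol=1e-12)


def _sym_from_vec(vec, parc):
    mods = parc.module_ids
    mat = np.zeros((len(mods), len(mods)))
    k = 0
    for a in range(len(mods)):
        for b in range(a, len(mods)):
            mat[a, b] = mat[b, a] = vec[k]
            k += 1
    return mat


def test_zscore_unzscore_round_trip(parc_tiny):
    rng = np.random.default_rng(4)
    recs = []
    for s in range(4):
        m = rng.uniform(0.2, 0.8, (4, 4))
        m = (m + m.T) / 2
        recs.append({"alpha": ConnectivityRecord(
            f"c{s}", "alpha", "module", parc_tiny.module_ids, m)})
    ref = build_control_reference(recs)
    subj = recs[0]
    z = zscore_subject(subj, ref).z["alpha"]
    _, orig = vectorize_connections(subj["alpha"])
    recovered = z * ref.sd["alpha"] + ref.mean["alpha"]
    assert np.allclose(recovered, orig, atol=1e-12)


def test_control_cohort_zscored_against_itself_averages_zero(parc_tiny):
    rng = np.random.default_rng(5)
    recs = []
    for s in range(6):
        m = rng.uniform(0.2, 0.8, (4, 4))
        m = (m + m.T) / 2
        recs.append({"alpha": ConnectivityRecord(
            f"c{s}", "alpha", "module", parc_tiny.module_ids, m)})
    ref = build_control_reference(recs)
    zs = np.vstack([zscore_subject(r, ref).z["alpha"] for r in recs])
    assert np.allclose(zs.mean(axis=0), 0.0, atol=1e-10)


def test_missing_band_in_reference_is_an_error(parc_tiny):
    recs = []
    rng = np.random.default_rng(6)
    for s in range(2):
        m = rng.uniform(0.2, 0.8, (4, 4))
        m = (m + m.T) / 2
        recs.append({"alpha": ConnectivityRecord(
            f"c{s}", "alpha", "module", parc_tiny.module_ids, m)})
    ref = build_control_reference(recs)
    subj = {"theta": recs[0]["alpha"]}
    with pytest.raises(KeyError, match="theta"):
        zscore_subject(subj, ref)


# ---------------------------------------------------------------------------
# summary features

def test_global_features_hand_values(parc_tiny):
    pairs = [(i, j) for a, i in enumerate(parc_tiny.module_ids)
             for j in parc_tiny.module_ids[a:]]
    z = np.zeros(len(pairs))
    z[:3] = [-1.0, 0.0, 1.0]
    nfc = NormalizedFC("s", pairs, {"alpha": z[:3]})
    nfc.pairs = pairs[:3]
    mean, sd = global_features(nfc)["alpha"]
    assert mean == pytest.approx(0.0)
    assert sd == pytest.approx(1.0)


def test_global_mean_shifts_with_constant_offset(parc_tiny):
    rng = np.random.default_rng(7)
    pairs = [(i, j) for a, i in enumerate(parc_tiny.module_ids)
             for j in parc_tiny.module_ids[a:]]
    z = rng.normal(size=len(pairs))
    m0, s0 = global_features(NormalizedFC("s", pairs, {"a": z}))["a"]
    m1, s1 = global_features(NormalizedFC("s", pairs, {"a": z + 2.5}))["a"]
    assert m1 == pytest.approx(m0 + 2.5)
    assert s1 == pytest.approx(s0)


def test_hemispheric_feature_hand_example(parc_tiny):
    # modules 0,1 are L and 2,3 are R; intra-L z = 1, intra-R z = 0
    zmap = {(0, 0): 1.0, (0, 1): 1.0, (1, 1): 1.0,
            (2, 2): 0.0, (2, 3): 0.0, (3, 3): 0.0,
            (0, 2): 5.0, (0, 3): 5.0, (1, 2): 5.0, (1, 3): 5.0}
    nfc = _nfc(parc_tiny, zmap)
    assert hemispheric_feature(nfc, ["L", "R"], parc_tiny)["alpha"] == 0.5
    assert hemispheric_feature(nfc, ["L"], parc_tiny)["alpha"] == 1.0
    with pytest.raises(ValueError, match="nonempty"):
        hemispheric_feature(nfc, [], parc_tiny)


def test_constant_z_gives_constant_regional_means(parc_tiny):
    pairs = [(i, j) for a, i in enumerate(parc_tiny.module_ids)
             for j in parc_tiny.module_ids[a:]]
    nfc = NormalizedFC("s", pairs, {"alpha": np.full(len(pairs), 0.7)})
    assert hemispheric_feature(nfc, ["L"], parc_tiny)["alpha"] == pytest.approx(0.7)
    lobe = parc_tiny.lobe_of(parc_tiny.module_ids[0])
    assert lobar_feature(nfc, [lobe], parc_tiny)["alpha"] == pytest.approx(0.7)


def test_lobar_feature_averages_across_lobes():
    parc = make_parcellation(8, 4, lobe_names=("frontal", "temporal"))
    # L hemisphere: module 0 frontal, module 1 temporal (singletons per region)
    zmap = {(0, 0): 0.1, (1, 1): 0.5}
    nfc = _nfc(parc, zmap)
    single = lobar_feature(nfc, ["frontal"], parc, lead_hemispheres=["L"])
    assert single["alpha"] == pytest.approx(0.1)
    both = lobar_feature(nfc, ["frontal", "temporal"], parc,
                         lead_hemispheres=["L"])
    assert both["alpha"] == pytest.approx(0.3)


def test_lobar_feature_rejects_unknown_lobe(parc_tiny):
    nfc = _nfc(parc_tiny, {})
    with pytest.raises(ValueError, match="not present"):
        lobar_feature(nfc, ["cerebellum"], parc_tiny)


def test_feature_table_has_one_row_per_subject_band(parc_tiny):
    nfcs = [_nfc(parc_tiny, {(0, 1): 1.0}, subject=f"p{k}") for k in range(3)]
    leads = {f"p{k}": (("L",), (parc_tiny.lobes[0],)) for k in range(3)}
    table = feature_table(nfcs, leads, parc_tiny)
    assert len(table) == 3  # one band in these records
    assert set(table.columns) >= {"global_mean", "global_sd",
                                  "hemispheric_mean", "lobar_mean"}
    assert np.isfinite(table["hemispheric_mean"]).all()
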