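import numpy as np
import pytest

from cytodx import fcs_io as fio
from cytodx.fcs_io import (
    EventMatrix,
    FcsCorruptError,
    FcsFormatError,
    LogicleParams,
    SpilloverMatrix,
    biexponential,
    compensate,
    estimate_logicle,
    logicle,
    read_fcs,
    write_fcs,
)


def make_events(rng, n=100, c=5, channels=None):
    channels = channels or [f"FL{i}" for i in range(c)]
    return EventMatrix(rng.uniform(1, 1000, (n, len(channels))), channels)


class TestFcsRoundTrip:
    def test_write_read_identity(self, rng, tmp_path):
        E = make_events(rng)
        E.marker_map = {"FL0": "CD3", "FL1": "CD19"}
        path = tmp_path / "a.fcs"
        write_fcs(E, path)
        E2 = read_fcs(path)
        assert E2.channels == E.channels
        assert E2.marker_map == E.marker_map
        np.testing.assert_allclose(E2.values, E.values, rtol=1e-6)

    def test_slash_in_channel_name_preserved(self, rng, tmp_path):
        E = make_events(rng, channels=["FSC-A", "iNKT/CD34"])
        path = tmp_path / "b.fcs"
        write_fcs(E, path)
        assert read_fcs(path).channels == ["FSC-A", "iNKT/CD34"]

    def test_single_zero_value(self, tmp_path):
        E = EventMatrix(np.array([[0.0]]), ["FL1"], ranges={"FL1": 1024.0})
        path = tmp_path / "c.fcs"
        write_fcs(E, path)
        E2 = read_fcs(path)
        assert E2.values[0, 0] == 0.0
        assert E2.ranges["FL1"] == 1024.0

    def test_empty_matrix_rejected(self, tmp_path):
        E = EventMatrix(np.empty((0, 2)), ["a", "b"])
        with pytest.raises(ValueError):
            write_fcs(E, tmp_path / "d.fcs")


def craft_fcs_31(values, channels, tot=None):
    """Assemble FCS 3.1 bytes from scratch, independently of write_fcs."""
    values = np.asarray(values, dtype="<f4")
    tot = values.shape[0] if tot is None else tot
    data = values.tobytes()
    d = "/"
    kw = f"/$MODE/L/$DATATYPE/F/$BYTEORD/1,2,3,4/$TOT/{tot}/$PAR/{values.shape[1]}"
    for j, ch in enumerate(channels, 1):
        kw += f"/$P{j}N/{ch}/$P{j}B/32/$P{j}E/0,0"
    kw += "/"
    text = kw.encode()
    text_start = 58
    data_start = text_start + len(text)
    header = b"FCS3.1    " + b"".join(
        f"{x:>8d}".encode()
        for x in (
            text_start,
            text_start + len(text) - 1,
            data_start,
            data_start + len(data) - 1,
            0,
            0,
        )
    )
    return header + text + data


class TestFcsParsing:
    def test_handcrafted_fixture_bytes(self, tmp_path):
        vals = np.array([[1.5, 2.5], [3.0, -4.0], [100.0, 0.25]])
        blob = craft_fcs_31(vals, ["FL1", "FL2"])
        path = tmp_path / "crafted.fcs"
        path.write_bytes(blob)
        E = read_fcs(path)
        assert E.channels == ["FL1", "FL2"]
        np.testing.assert_allclose(E.values, vals, rtol=1e-6)

    def test_tot_mismatch_is_corrupt(self, tmp_path):
        vals = np.arange(18, dtype=float).reshape(9, 2)
        blob = craft_fcs_31(vals, ["a", "b"], tot=10)
        path = tmp_path / "bad.fcs"
        path.write_bytes(blob)
        with pytest.raises(FcsCorruptError):
            read_fcs(path)

    def test_unsupported_version(self, tmp_path):
        blob = craft_fcs_31(np.ones((2, 1)), ["a"])
        path = tmp_path / "old.fcs"
        path.write_bytes(b"FCS2.0" + blob[6:])
        with pytest.raises(FcsFormatError):
            read_fcs(path)

    def test_spillover_keyword(self, tmp_path, rng):
        E = make_events(rng, channels=["FL1", "FL2"])
        path = tmp_path / "spill.fcs"
        write_fcs(E, path)
        # crafted file with an explicit $SPILLOVER keyword
        d = "/$SPILLOVER/2,FL1,FL2,1,0.1,0.2,1"
        crafted = craft_fcs_31(np.ones((1, 2)), ["FL1", "FL2"])
        # inject the keyword by rebuilding text
        text_start = 58
        te = int(crafted[18:26])
        text = crafted[text_start : te + 1].decode()
        text = text + d[1:] + "/"
        data = crafted[int(crafted[26:34]) :]
        data_start = text_start + len(text)
        header = b"FCS3.1    " + b"".join(
            f"{x:>8d}".encode()
            for x in (
                text_start,
                text_start + len(text) - 1,
                data_start,
                data_start + len(data) - 1,
                0,
                0,
            )
        )
        path2 = tmp_path / "spill2.fcs"
        path2.write_bytes(header + text.encode() + data)
        S = fio.read_spillover(path2)
        assert S.channels == ["FL1", "FL2"]
        np.testing.assert_allclose(S.matrix, [[1, 0.1], [0.2, 1]])


class TestCompensation:
    def test_identity_spillover(self, rng):
        E = make_events(rng, c=3)
        S = SpilloverMatrix(np.eye(3), E.channels)
        out = compensate(E, S)
        np.testing.assert_allclose(out.values, E.values)

    def test_closed_form_2x2(self):
        # oracle: explicit 2x2 inverse, inv([[a,b],[c,d]]) = [[d,-b],[-c,a]]/det
        S_mat = np.array([[1.0, 0.1], [0.2, 1.0]])
        det = 1.0 - 0.1 * 0.2
        inv = np.array([[1.0, -0.1], [-0.2, 1.0]]) / det
        expected = np.array([[10.0, 2.0]]) @ inv
        E = EventMatrix([[10.0, 2.0]], ["A", "B"])
        out = compensate(E, SpilloverMatrix(S_mat, ["A", "B"]))
        np.testing.assert_allclose(out.values, expected)

    def test_scaled_identity_halves(self, rng):
        E = make_events(rng, c=2)
        out = compensate(E, SpilloverMatrix(2 * np.eye(2), E.channels))
        np.testing.assert_allclose(out.values, E.values / 2)

    def test_double_compensation_inverts(self, rng):
        E = make_events(rng, c=3)
        S = np.eye(3) + rng.uniform(0, 0.2, (3, 3)) * (1 - np.eye(3))
        out = compensate(E, SpilloverMatrix(S, E.channels))
        back = compensate(out, SpilloverMatrix(np.linalg.inv(S), E.channels))
        np.testing.assert_allclose(back.values, E.values, atol=1e-6)

    def test_singular_matrix_diagnosed(self, rng):
        E = make_events(rng, c=2)
        with pytest.raises(np.linalg.LinAlgError):
            compensate(E, SpilloverMatrix(np.ones((2, 2)), E.channels))

    def test_untouched_channels(self, rng):
        E = make_events(rng, c=3)
        S = SpilloverMatrix(2 * np.eye(2), E.channels[:2])
        out = compensate(E, S)
        np.testing.assert_allclose(out.values[:, 2], E.values[:, 2])


class TestLogicleEstimation:
    def test_w_formula(self):
        # oracle: evaluate W = (M - log10(T/|r|)) / 2 numerically
        T, M = 262144.0, 4.5
        neg = np.full(100, -1000.0)  # 5th percentile of negatives = -1000
        pos = np.linspace(1, T, 100)
        E = EventMatrix(
            np.concatenate([neg, pos]).reshape(-1, 1), ["FL1"], ranges={"FL1": T}
        )
        p = estimate_logicle(E, "FL1")
        assert p.T == T and p.M == 4.5 and p.A == 0.0
        assert p.W == pytest.approx((M - np.log10(T / 1000.0)) / 2, rel=1e-12)

    def test_all_positive_default_w(self, rng):
        E = EventMatrix(
            rng.uniform(1, 100, (50, 1)), ["FL1"], ranges={"FL1": 262144.0}
        )
        assert estimate_logicle(E, "FL1").W == 0.5

    def test_w_clamped_at_zero(self):
        # negatives tiny relative to T (|r| < T * 10^-M) drive the formula
        # negative -> clamp to 0
        T = 262144.0
        vals = np.concatenate([np.full(50, -1e-3), np.linspace(1, T, 50)])
        E = EventMatrix(vals.reshape(-1, 1), ["FL1"], ranges={"FL1": T})
        assert estimate_logicle(E, "FL1").W == 0.0

    def test_nonpositive_range_rejected(self):
        E = EventMatrix([[1.0]], ["FL1"], ranges={"FL1": 0.0})
        with pytest.raises(ValueError):
            estimate_logicle(E, "FL1")


class TestLogicleTransform:
    P = LogicleParams(T=262144.0, M=4.5, W=0.5, A=0.0)

    def test_top_of_scale_maps_to_one(self):
        E = EventMatrix([[262144.0]], ["FL1"])
        out = logicle(E, {"FL1": self.P})
        assert out.values[0, 0] == pytest.approx(1.0, abs=1e-8)
        assert out.transformed[0]

    def test_forward_inverse_round_trip(self):
        grid = np.linspace(-1000.0, 262144.0, 1000)
        E = EventMatrix(grid.reshape(-1, 1), ["FL1"])
        y = logicle(E, {"FL1": self.P}).values[:, 0]
        back = biexponential(y, self.P)
        np.testing.assert_allclose(back, grid, rtol=1e-6, atol=1e-4)

    def test_strictly_monotone(self, rng):
        # brute-force: dense tabulation of the forward function is monotone,
        # therefore transformed random pairs must preserve order
        x = np.sort(rng.uniform(-500, 262144, 500))
        E = EventMatrix(x.reshape(-1, 1), ["FL1"])
        y = logicle(E, {"FL1": self.P}).values[:, 0]
        assert np.all(np.diff(y) > 0)
        dense = biexponential(np.linspace(-0.2, 1.1, 4000), self.P)
        assert np.all(np.diff(dense) > 0)

    def test_zero_maps_into_unit_interval_when_w_positive(self):
        E = EventMatrix([[0.0]], ["FL1"])
        y = logicle(E, {"FL1": self.P}).values[0, 0]
        assert 0.0 < y < 1.0

    def test_param_validation(self):
        with pytest.raises(ValueError):
            LogicleParams(T=-1.0)
        with pytest.raises(ValueError):
            LogicleParams(T=100.0, W=3.0)  # W > M/2

    def test_double_transform_rejected(self):
        E = EventMatrix([[1.0]], ["FL1"])
        out = logicle(E, {"FL1": self.P})
        with pytest.raises(ValueError):
            logicle(out, {"FL1": self.P})


class TestStandardTransform:
    def test_scatter_linear_fluor_logicle(self, rng):
        n = 200
        vals = np.column_stack(
            [
                rng.uniform(0, 262144, n),  # FSC-A
                rng.uniform(-100, 262144, n),  # fluorescence
                np.cumsum(rng.exponential(1, n)),  # Time
            ]
        )
        E = EventMatrix(
            vals,
            ["FSC-A", "CD3", "Time"],
            ranges={"FSC-A": 262144.0, "CD3": 262144.0},
        )
        out = fio.standard_transform(E)
        np.testing.assert_allclose(out.column("FSC-A"), vals[:, 0] / 262144.0)
        assert out.transformed[0] and out.transformed[1]
        assert not out.transformed[2]  # Time untouched
        np.testing.assert_allclose(out.column("Time"), vals[:, 2])
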