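"""Architecture dialect: shape propagation, depth, and parameter accounting."""

import dataclasses

import pytest

from diatomnet import archspec as A


# Independent closed-form oracle: per-layer sums written out longhand, kept
# deliberately separate from the count_parameters implementation.
def _conv(k, ci, co):
    return k * k * ci * co + co


def _inception(ci, c1, r3, c3, r5, c5, pp):
    return (
        _conv(1, ci, c1)
        + _conv(1, ci, r3)
        + _conv(3, r3, c3)
        + _conv(1, ci, r5)
        + _conv(5, r5, c5)
        + _conv(1, ci, pp)
    )


EXPECTED_TOTAL = (
    _conv(7, 3, 64)
    + _conv(1, 64, 64)
    + _conv(3, 64, 192)
    + _inception(192, 64, 96, 128, 16, 32, 32)
    + _inception(256, 192, 96, 208, 16, 48, 64)
    + _inception(512, 384, 192, 384, 48, 128, 128)
    + (1024 * 68 + 68)
)

PRINTED_ROWS = {
    "conv1": (216, 64, 64),
    "pool1": (108, 32, 64),
    "conv2": (108, 32, 192),
    "pool2": (54, 16, 192),
    "inception1": (54, 16, 256),
    "pool3": (27, 8, 256),
    "inception2": (27, 8, 512),
    "pool4": (13, 4, 512),
    "pool5": (6, 2, 1024),
    "avgpool": (1, 1, 1024),
    "fc": (1, 1, 68),
}


@pytest.fixture(scope="module")
def default_spec():
    return A.default_diatomnet_spec()


class TestDefaultSpec:
    def test_depth_sums_to_ten(self, default_spec):
        assert default_spec.depth == 10

    def test_first_inception_branch_widths(self, default_spec):
        inc = next(l for l in default_spec.layers if l.kind == "inception")
        assert inc.inception.as_tuple() == (64, 96, 128, 16, 32, 32)

    def test_dropout_rate(self, default_spec):
        drop = next(l for l in default_spec.layers if l.kind == "dropout")
        assert drop.rate == pytest.approx(0.40)

    def test_input_contract(self, default_spec):
        assert (default_spec.input_height, default_spec.input_width) == (432, 128)
        assert default_spec.num_classes == 68


class TestShapeTrace:
    @pytest.mark.parametrize("label,expected", sorted(PRINTED_ROWS.items()))
    def test_printed_output_sizes(self, default_spec, label, expected):
        assert A.trace_shapes(default_spec).by_label()[label] == expected

    def test_one_by_one_convolution_preserves_spatial_size(self):
        layers = (
            A.LayerSpec(
                kind="convolution",
                label="pw",
                patch=(1, 1),
                stride=1,
                padding_mode="same",
                out_channels=7,
                depth_contribution=1,
            ),
            A.LayerSpec(kind="linear", label="fc", out_channels=2, depth_contribution=1),
            A.LayerSpec(kind="softmax", label="sm"),
        )
        spec = A.ArchitectureSpec(
            input_height=33, input_width=21, input_channels=5, num_classes=2, layers=layers
        )
        assert A.trace_shapes(spec).by_label()["pw"] == (33, 21, 7)

    def test_underflow_names_offending_layer(self):
        layers = (
            A.LayerSpec(
                kind="avg_pool",
                label="too_big",
                patch=(50, 50),
                stride=1,
                padding_mode="valid_floor",
            ),
            A.LayerSpec(kind="linear", label="fc", out_channels=2, depth_contribution=1),
            A.LayerSpec(kind="softmax", label="sm"),
        )
        spec = A.ArchitectureSpec(
            input_height=10, input_width=10, input_channels=1, num_classes=2, layers=layers
        )
        with pytest.raises(A.ShapeUnderflowError, match="too_big"):
            A.trace_shapes(spec)


class TestParameterCount:
    def test_total_matches_independent_closed_form(self, default_spec):
        assert A.count_parameters(default_spec).total == EXPECTED_TOTAL

    def test_total_millions_rounds_to_published_budget(self, default_spec):
        assert A.count_parameters(default_spec).total_millions_2dp == 1.85

    def test_single_linear_layer_closed_form(self):
        layers = (
            A.LayerSpec(kind="linear", label="fc", out_channels=68, depth_contribution=1),
            A.LayerSpec(kind="softmax", label="sm"),
        )
        spec = A.ArchitectureSpec(
            input_height=1, input_width=1, input_channels=1024, num_classes=68, layers=layers
        )
        assert A.count_parameters(spec).total == 1024 * 68 + 68

    @pytest.mark.parametrize("padding_mode,pool", [("same", 13), ("valid_floor", 11)])
    def test_count_invariant_to_padding_mode(self, padding_mode, pool):
        # padding moves spatial sizes, never weights: with a global average
        # pool ahead of the head, both variants count identically
        layers = (
            A.LayerSpec(
                kind="convolution",
                label="c",
                patch=(3, 3),
                stride=1,
                padding_mode=padding_mode,
                out_channels=6,
                depth_contribution=1,
            ),
            A.LayerSpec(
                kind="avg_pool", label="gap", patch=(pool, pool), stride=1, padding_mode="valid_floor"
            ),
            A.LayerSpec(kind="linear", label="fc", out_channels=3, depth_contribution=1),
            A.LayerSpec(kind="softmax", label="sm"),
        )
        spec = A.ArchitectureSpec(
            input_height=13, input_width=13, input_channels=2, num_classes=3, layers=layers
        )
        assert A.count_parameters(spec).total == (9 * 2 * 6 + 6) + (6 * 3 + 3)

    @pytest.mark.parametrize(
        "field", ["one_by_one", "three_reduce", "three_by_three", "five_reduce", "five_by_five", "pool_proj"]
    )
    def test_monotone_in_every_inception_width(self, default_spec, field):
        base = A.count_parameters(default_spec).total
        bumped_layers = []
        bumped_once = False
        for l in default_spec.layers:
            if l.kind == "inception" and not bumped_once:
                cfg = dataclasses.replace(l.inception, **{field: getattr(l.inception, field) + 1})
                bumped_layers.append(dataclasses.replace(l, inception=cfg))
                bumped_once = True
            else:
                bumped_layers.append(l)
        bumped = dataclasses.replace(default_spec, layers=tuple(bumped_layers))
        assert A.count_parameters(bumped).total > base

    def test_inception_channel_conservation(self, default_spec):
        outs = [
            l.inception.concat_channels for l in default_spec.layers if l.kind == "inception"
        ]
        assert outs == [256, 512, 1024]


class TestTableValidation:
    def test_default_spec_has_no_discrepancies(self, default_spec):
        assert A.validate_against_table(A.trace_shapes(default_spec)) == []

    def test_removing_reconciliation_pool_breaks_only_downstream_rows(self, default_spec):
        layers = tuple(l for l in default_spec.layers if l.label != "pool5")
        spec = dataclasses.replace(default_spec, layers=layers)
        issues = A.validate_against_table(A.trace_shapes(spec))
        assert issues, "dropping the reconciliation pool must be detected"
        upstream = {"conv1", "pool1", "conv2", "pool2", "inception1", "pool3", "inception2", "pool4"}
        assert all(d.label not in upstream for d in issues)
        assert {d.label for d in issues} >= {"inception3", "avgpool"}

    def test_trace_equal_to_expectations_by_construction(self, default_spec):
        trace = A.trace_shapes(default_spec)
        assert A.validate_against_table(trace) == []


class TestSerialization:
    def test_yaml_round_trip(self, default_spec):
        assert A.spec_from_yaml(A.spec_to_yaml(default_spec)) == default_spec

    def test_reduced_spec_round_trip(self):
        spec = A.reduced_diatomnet_spec(5)
        assert A.spec_from_yaml(A.spec_to_yaml(spec)) == spec


class TestValidation:
    def test_inception_config_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            A.InceptionConfig(0, 96, 128, 16, 32, 32)

    def test_spec_requires_linear_then_softmax_tail(self):
        with pytest.raises(ValueError):
            A.ArchitectureSpec(
                input_height=8,
                input_width=8,
                input_channels=1,
                num_classes=2,
                layers=(
                    A.LayerSpec(kind="linear", label="fc", out_channels=2, depth_contribution=1),
                ),
            )

    def test_dropout_rate_bounds(self):
        with pytest.raises(ValueError):
            A.LayerSpec(kind="dropout", label="d", rate=1.5)
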