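"""Serial versus parallel chains seen through dual reporters.

Two promoters that hang off one causal chain respond in a strict temporal
order with correlated timing in every cell; promoters driven by
independent chains show neither.  The subsample-averaged Pearson
correlation and the strict-order permutation test distinguish the two
architectures from simulated dual-reporter colonies.
"""

from stresstiming import (
    ChainSpec,
    DualChainSpec,
    ReporterSpec,
    SimConfig,
    StatsConfig,
    compute_expression,
    generate_dataset,
    response_times,
)
from stresstiming.pipeline import pair_summary

ARCHITECTURES = {
    "serial": DualChainSpec(
        architecture="serial", shared=ChainSpec(6, 1.5), mid=ChainSpec(3, 1.0)
    ),
    "parallel": DualChainSpec(
        architecture="parallel",
        independent_a=ChainSpec(8, 1.5),
        independent_b=ChainSpec(4, 2.0),
    ),
}

for name, chain in ARCHITECTURES.items():
    config = SimConfig(
        n_founders=40,
        seed=11,
        growth_rate_mean=0.35,
        growth_rate_sd=0.0,
        pre_stress_duration=0.5,
        post_stress_duration=6.0,
        frame_interval=1 / 6,
        chain=chain,
        reporters={
            "a": ReporterSpec(maturation_time=0.0, decay_rate=3.0),
            "b": ReporterSpec(maturation_time=0.0, decay_rate=3.0),
        },
    )
    table, _, _ = generate_dataset(config)
    rt = response_times(compute_expression(table))
    res = pair_summary(table, rt, StatsConfig(n_subsamples=300, seed=2))
    print(
        f"{name:>8s}: r = {res.r_mean:+.2f} +/- {res.r_sd:.2f}, "
        f"ordered fraction = {res.order_fraction:.2f}, "
        f"permutation P = {res.permutation_p:.3f}"
    )
print("serial chains give strict order (fraction 1) and low P; parallel do not")
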