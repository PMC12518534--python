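"""Budget calibration scan for the default architecture.

The stage widths are geometric ([C, 2C, 4C], forced by the channel-
halving patch expander), so the base width C and the bottleneck FFN
expansion are the free knobs. This script tabulates trainable parameters
and forward GFLOPs at 224x224 over that grid; the shipped defaults
(C=160, bottleneck expansion 6) are the row landing within 1% of 42.02M
parameters and 5% of 18.47 GFLOPs.

Run:  python scripts/calibrate_budget.py [--widths 128 160 176] [--expansions 4 6]
"""

import argparse

from dcfnet.config import ModelConfig, StagePlan
from dcfnet.network import build_model, count_flops, count_parameters

TARGET_PARAMS_M = 42.02
TARGET_GFLOPS = 18.47


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--widths", type=int, nargs="+", default=[128, 144, 160, 176])
    ap.add_argument("--expansions", type=int, nargs="+", default=[4, 6])
    args = ap.parse_args()
    print(f"{'C':>5} {'bneck_ffn':>9} {'params (M)':>11} {'dP%':>7} {'GFLOPs':>8} {'dF%':>7}")
    for c in args.widths:
        for e in args.expansions:
            cfg = ModelConfig(
                stage_plan=StagePlan(channels_per_stage=(c, 2 * c, 4 * c)),
                bottleneck_ffn_expansion=e,
            )
            model = build_model(cfg, seed=0)
            pm = count_parameters(model) / 1e6
            gf = count_flops(model)
            dp = 100 * (pm - TARGET_PARAMS_M) / TARGET_PARAMS_M
            df = 100 * (gf - TARGET_GFLOPS) / TARGET_GFLOPS
            flag = " <-- in band" if abs(dp) <= 1 and abs(df) <= 5 else ""
            print(f"{c:>5} {e:>9} {pm:>11.3f} {dp:>+7.2f} {gf:>8.3f} {df:>+7.2f}{flag}")


if __name__ == "__main__":
    main()
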