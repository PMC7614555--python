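"""Power of the cohort for simple correlational analyses.

Reports the two-sided power at the usable sample size and the smallest
detectable correlation at 80% power, via the Fisher z approximation.
"""

import argparse

from cohortnet.preprocess import correlation_power, min_detectable_r


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--n", type=int, default=519)
    ap.add_argument("--alpha", type=float, default=0.05)
    args = ap.parse_args()

    r_min = min_detectable_r(args.n, power=0.80, alpha=args.alpha)
    print(f"n = {args.n}, alpha = {args.alpha}")
    print(f"smallest correlation detectable with 80% power: "
          f"{r_min:.4f} (~{r_min:.2f})")
    for r in (0.10, 0.12, 0.15, 0.20):
        print(f"  power at r = {r:.2f}: "
              f"{correlation_power(r, args.n, args.alpha):.3f}")


if __name__ == "__main__":
    main()
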