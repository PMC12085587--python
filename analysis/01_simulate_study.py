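#!/usr/bin/env python
"""Generate the synthetic study: daily environments for the twelve reference
reef locations and annual growth tables for the spatial compilation and the
eleven-core interannual subset.

Writes results/study/env/<site>.csv, growth_interannual.csv,
growth_spatial.csv and a truth summary, all at a fixed seed.
"""

from pathlib import Path

from coralchron import io as cio
from coralchron import study

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "study"


def main() -> None:
    (OUT / "env").mkdir(parents=True, exist_ok=True)
    spatial = study.generate_study(SEED, subset="spatial")
    interannual = study.generate_study(SEED, subset="interannual")
    for loc, env in spatial["env"].items():
        cio.write_env_csv(env, OUT / "env" / f"{loc.replace(' ', '_')}.csv")
    cio.write_growth_csv(spatial["growth"], OUT / "growth_spatial.csv")
    cio.write_growth_csv(interannual["growth"], OUT / "growth_interannual.csv")
    interannual["truth"].covariates.to_csv(OUT / "annual_covariates.csv",
                                           index=False)
    g = spatial["growth"]
    print(f"spatial: {g.core_id.nunique()} cores, "
          f"{g.location_id.nunique()} locations, {len(g)} core-years")
    means = g.groupby("location_id").extension_cm.mean().sort_values()
    print("site mean extension (cm/yr):")
    print(means.round(2).to_string())
    print(f"gradient spans {means.min():.2f}-{means.max():.2f} cm/yr across "
          f"K_d490 0.035-0.070 m^-1, as in the observed system")


if __name__ == "__main__":
    main()
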