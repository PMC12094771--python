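# warconj

Consumer-resource ODE models of bacterial warfare with horizontal transfer
of the weapon itself.

Many bacterial toxins — colicins among them — are encoded on conjugative
or mobilizable plasmids together with their immunity genes. During a
contest, the attacker's weapon system can therefore transfer *into* the
strain it is attacking, converting targets into immune, toxin-producing
transconjugants. `warconj` asks when that transfer matters: it simulates
batch competitions between an attacker (`C1`), a sensitive target (`C2`)
and emerging transconjugants (`C3`) under Monod-limited growth on shared
(and optionally private) nutrients, toxin-mediated killing with Hill
coefficient 1, and nutrient-gated conjugation:

    dC1/dt = C1 rC1 M1 (1 − γ)
    dC2/dt = C2 rC2 M1 − b C2 (C1 + C3) M1 − E C2 T/(T + KC2T)
    dC3/dt = C3 rC3 M1 (1 − γ) + b C2 (C1 + C3) M1
    dT/dt  = γ (C1 + C3) M1 − C2 T/(T + KC2T)
    dN1/dt = − M1 (C1 + C2 + C3),          M1 = N1/(N1 + KN1)

A second variant adds private nutrients (`N2` for the attacker, `N3` for
the target lineage) to model metabolic niche separation; see
[docs/methods.md](docs/methods.md) for the full equations, parameter
table, numerical choices and limitations. The package is aimed at
microbial ecologists and evolutionary biologists who want steady-state
strain frequencies across parameter space (toxin potency, conjugation
rate, inoculum composition and density, niche separation) without writing
their own integration and sweep machinery.

## Worked example

Compare the three contest scenarios at the default parameter table,
starting from a 1:1:0 attacker:target:transconjugant inoculum:

```python
from warconj import ModelVariant, Scenario, run_scenario

for scenario in Scenario:
    r = run_scenario(scenario, ModelVariant.DEFAULT)
    print(f"{scenario.value:21s} attacker={r.f_attacker:.4f} "
          f"target={r.f_target:.4f} transconjugant={r.f_transconjugant:.4f}")
```

prints

```
killing_only          attacker=1.0000 target=0.0000 transconjugant=0.0000
transfer_only         attacker=0.3526 target=0.5917 transconjugant=0.0557
killing_and_transfer  attacker=0.9587 target=0.0000 transconjugant=0.0413
```

Killing alone leaves a pure attacker population. Transfer alone converts
about 5.6% of the community into transconjugants while all three
genotypes persist. With killing *and* transfer, transconjugants still
emerge — the weapon does spread into the opposing lineage — but at a lower
frequency (4.1%), because most potential recipients are killed before
they can be converted. Re-running the last scenario with
`ModelVariant.METABOLIC_DIVERSITY` (private nutrients for each lineage)
raises the transconjugant frequency to 0.3387: a converted target that
can grow on a nutrient the attacker cannot touch escapes competitive
suppression.

The same computations are available from the shell:

```sh
warconj scenario --variant metabolic_diversity --scenario killing_and_transfer
warconj run --scenario killing_only -o trajectory.csv
warconj sweep -a b=0:1:21 -a E=log:0.1:50:21 -o grid.csv --plot grid.png
```

`run` writes a full trajectory (columns `t,C1,C2,C3,N1,N2,N3,T`), `sweep`
writes one row per grid cell with complete parameter provenance, and every
command accepts a YAML config file (`--config`) whose keys mirror the
packaged defaults in `src/warconj/data/defaults.yaml`.

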