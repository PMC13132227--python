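# flocklearn

Analysis toolkit for two-option cultural diffusion experiments in wild,
individually marked animal populations — built around the study design in
which a novel food (dyed red or blue) is introduced to several communal
roosts of urban parrots, seeded by a handful of trained demonstrators, and
its uptake, colour choice and handling technique are tracked across the
social network.

It is aimed at behavioural ecologists who run open diffusion experiments
and want the full statistical chain as tested, scriptable Python:

1. **Association networks** — the simple ratio index (SRI) under the gambit
   of the group: for a dyad, `SRI = x / (x + y_i + y_j)`, the proportion of
   group scans containing either bird in which both were present; plus
   between-roost movement rates `m_AB = n_ov / (n_A + n_B − n_ov)` and
   roost-membership assignment from pre-dawn counts.
2. **Order-of-acquisition diffusion analysis (OADA / NBDA)** — each naive
   individual `i` acquires at rate
   `R_i = exp(Γ·x_i)·s·Σ_j a_ij z_j + exp(B·x_i)`, with `s` the social
   transmission rate per unit network connection `a_ij`, `z_j` the informed
   status of `j`, and individual-level variables `x_i` (sex, age) acting
   independently on the social and asocial rates.  The baseline hazard
   cancels from the order likelihood.  Models in every ILV combination,
   with and without the network, are compared by AICc and Akaike weights,
   and the fitted social model yields the estimated percentage of learning
   events due to social transmission (%ST) with a profile-likelihood CI.
3. **Experience-weighted attraction (EWA) choice models** — the probability
   that bird `j` picks colour `i` is `(1−γ_j)·I_ij + γ_j·S_ij`, where
   `I = softmax(λ_j A_j)` over payoff-updated attraction scores
   `A ← (1−φ)A + φπ`, and `S` is built from the demonstrations witnessed in
   the preceding 60 s: frequency dependence `S_k ∝ N_k^f` (f > 1 =
   conformity), male-/adult-biased counts, or a same-roost cue weight
   `exp(β)`.  Every learning parameter gets a hierarchical (age × sex) cell
   mean plus individual varying effects, sampled with an in-package
   gradient-based HMC; the five strategy models are compared by WAIC.
4. **Opening-technique analysis** — categorical opening sequences
   (unshell / crack location / extraction method) are one-hot encoded,
   standardized and compared by Euclidean distance; partial Mantel
   permutation tests relate technique dissimilarity to individual identity,
   geographic distance, between-roost movement, association strength and
   relatedness; chi-square post hoc tests with Bonferroni correction handle
   category-by-group contrasts.
5. **Synthetic study generator** — every input the pipeline consumes can be
   generated with known ground truth (multi-roost population, fluid
   foraging subgroups, seeded diffusions, EWA-driven colour choices,
   spatially structured techniques), which is what the test suite and the
   acceptance script run on.

## Worked example

Simulate a three-roost diffusion seeded by trained demonstrators, build the
SRI network from group scans, and ask whether the spread followed the
network:

```python
import tempfile
from flocklearn import io
from flocklearn.nbda import (ModelSpec, aicc_model_table, family_support,
                             fit_oada, percent_social)
from flocklearn.network import build_sri_network
from flocklearn.synthetic import (SyntheticConfig, generate_experiment,
                                  generate_population, generate_scans,
                                  scans_to_groupscans)

cfg = SyntheticConfig(individuals_per_roost=20, n_scans=300, n_days=6,
                      mean_subgroup_size=12.0, master_seed=42)
roster = generate_population(cfg)
net = build_sri_network(scans_to_groupscans(generate_scans(cfg, roster)),
                        ids=list(roster["id"]))
print(f"network: {len(net)} birds, {int((net.weights > 0).sum()/2)} dyads")

diffusion_df, events_df, truth = generate_experiment(cfg, roster, net)
with tempfile.NamedTemporaryFile("w", suffix=".csv") as f:
    diffusion_df.to_csv(f.name, index=False)
    record = io.read_diffusion(f.name)

fits = [fit_oada(record, net, ModelSpec(social=True)),
        fit_oada(record, net, ModelSpec(social=False))]
table = aicc_model_table(fits)
st = percent_social(fits[0], record, net)
print(f"acquisition events: {record.n_events}")
print(f"social-model Akaike weight: {family_support(table)['social']:.3f}")
print(f"estimated %ST: {st['estimate']:.1f}% "
      f"(95% CI {st['ci'][0]:.1f}-{st['ci'][1]:.1f}%)")
```

Output:

```
network: 100 birds, 4683 dyads
acquisition events: 55
social-model Akaike weight: 1.000
estimated %ST: 100.0% (95% CI 85.2-100.0%)
```

The diffusion was generated with social transmission rate `s = 5`, so
essentially all acquisition events flow through network ties: the social
model takes all the Akaike weight and the social term accounts for nearly
every learning event, with the profile CI reflecting the 55-event sample.

The same chain is available from the shell:

```bash
flocklearn simulate --seed 42 --out data/
flocklearn network --scans data/scans.csv --individuals data/individuals.csv --out edges.csv
flocklearn nbda --network edges.csv --diffusion data/diffusion.csv \
    --individuals data/individuals.csv --out nbda_report.json
flocklearn ewa --events data/events.csv --individuals data/individuals.csv \
    --strategy frequency --out ewa_out/
flocklearn run --seed 42 --out pipeline_out/     # everything, one report
```

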