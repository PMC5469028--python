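"""Build a tailored two-condition trial set from a pretest discount rate.

Half the larger-later amounts cover 20.5-99.5 euros linearly; the other
half are drawn around each delay's indifference point (SD 4 euros), which
concentrates offers where a participant with the given pretest k is most
uncertain.  Episodic trials carry personal event tags; control delays are
sampled between one day and the longest event delay.
"""

from discountfit import DesignConfig, EpisodicEvent, build_trials, validate_trialset

events = [
    EpisodicEvent("vacation Paris", 45),
    EpisodicEvent("sister's wedding", 120),
    EpisodicEvent("dentist", 7),
    EpisodicEvent("concert", 200),
    EpisodicEvent("exam", 14),
]

trialset = build_trials(k=0.012, events=events, config=DesignConfig(n_trials=80, seed=7))
df = trialset.trials

print(df.head(8).to_string(index=False))
print(f"\n{len(df)} trials; "
      f"{(df.condition == 'episodic').sum()} episodic / "
      f"{(df.condition == 'control').sum()} control")
tail = df[df.amount_half == "tailored"]
print(f"tailored amounts: mean {tail.amount_ll.mean():.1f} EUR, "
      f"sd {tail.amount_ll.std():.1f} EUR (drawn around each delay's "
      "indifference point)")
print("\nInvariant report:")
print(validate_trialset(trialset).to_string(index=False))
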