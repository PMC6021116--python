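model decay
  species S = 10
  J0: S => ; k1*S
  k1 = 0.5
end

m1 = model decay
sim1 = simulate uniform(0, 2, 100)
sim1.relative_tolerance = 1e-10
sim1.absolute_tolerance = 1e-14
t1 = run sim1 on m1
report time, S
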