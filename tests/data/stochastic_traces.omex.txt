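model birth_death
  species X = 0
  J0: => X; k_birth
  J1: X => ; k_death*X
  k_birth = 10
  k_death = 0.1
  dummy = 0
end

m1 = model birth_death
sim1 = simulate uniform(0, 50, 100)
sim1.algorithm = gillespie
sim1.seed = 7
t1 = run sim1 on m1
t2 = repeat t1 for dummy in [0, 1, 2], reset=true
plot "three traces" t2.time vs t2.X
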