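model case2
  species Stgc = 0, Stgn = 0, StgPc = 1, StgPn = 0
  J0: => Stgc; ksstg
  J1: Stgc => ; kdstg*Stgc
  J2: Stgc -> Stgn; ktr*(Stgc - Stgn)
  J3: StgPc => Stgc; kdp*StgPc
  J4: StgPn => Stgn; kdp*StgPn
  ksstg = 0
  kdstg = 0
  ktr = 0.5
  kdp = 0.1
  E_1 = 0.2
  C = 1
  N := 1.95^C
  StgPT := StgPc + StgPn
  StgT := (1 - N*E_1)*Stgc + N*E_1*Stgn
  StringTotal := StgPT + StgT
end

m1 = model case2 with ksstg = 0.02, kdstg = 0.015, StgPc = 0
sim1 = simulate uniform(0, 50, 100)
t1 = run sim1 on m1
report time, StgT, StringTotal, N
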