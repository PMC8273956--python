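network sprinkler4 {
}
variable Cloudy {
  type discrete [ 2 ] { T, F };
}
variable Sprinkler {
  type discrete [ 2 ] { T, F };
}
variable Rain {
  type discrete [ 2 ] { T, F };
}
variable WetGrass {
  type discrete [ 2 ] { T, F };
}
probability ( Cloudy ) {
  table 0.5, 0.5;
}
probability ( Sprinkler | Cloudy ) {
  ( T ) 0.1, 0.9;
  ( F ) 0.5, 0.5;
}
probability ( Rain | Cloudy ) {
  ( T ) 0.8, 0.2;
  ( F ) 0.2, 0.8;
}
probability ( WetGrass | Sprinkler, Rain ) {
  ( T, T ) 0.99, 0.01;
  ( T, F ) 0.9, 0.1;
  ( F, T ) 0.9, 0.1;
  ( F, F ) 0, 1;
}
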