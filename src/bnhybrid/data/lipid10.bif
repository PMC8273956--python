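network lipid10 {
}
variable Gender {
  type discrete [ 2 ] { male, female };
}
variable Smoking {
  type discrete [ 2 ] { no, yes };
}
variable PhysicalActivity {
  type discrete [ 3 ] { Insufficient, Normal, Sufficient };
}
variable SaltIntake {
  type discrete [ 2 ] { <6g, ≥6g };
}
variable OilIntake {
  type discrete [ 2 ] { <25g, ≥25g };
}
variable BMI {
  type discrete [ 4 ] { <18.5, 18.5~, 24.0~, 28.0~ };
}
variable CentralObesity {
  type discrete [ 2 ] { no, yes };
}
variable Hyperlipidemia {
  type discrete [ 2 ] { no, yes };
}
variable Hypertension {
  type discrete [ 2 ] { no, yes };
}
variable Diabetes {
  type discrete [ 2 ] { no, yes };
}
probability ( Gender ) {
  table 0.489599299321, 0.510400700679;
}
probability ( Smoking | Gender ) {
  ( male ) 0.48, 0.52;
  ( female ) 0.97, 0.03;
}
probability ( PhysicalActivity | Gender ) {
  ( male ) 0.32, 0.4, 0.28;
  ( female ) 0.38, 0.4, 0.22;
}
probability ( SaltIntake ) {
  table 0.4, 0.6;
}
probability ( OilIntake ) {
  table 0.45, 0.55;
}
probability ( BMI | PhysicalActivity ) {
  ( Insufficient ) 0.04, 0.42, 0.36, 0.18;
  ( Normal ) 0.05, 0.47, 0.33, 0.15;
  ( Sufficient ) 0.06, 0.52, 0.32, 0.1;
}
probability ( CentralObesity | BMI ) {
  ( <18.5 ) 0.98, 0.02;
  ( 18.5~ ) 0.8, 0.2;
  ( 24.0~ ) 0.45, 0.55;
  ( 28.0~ ) 0.03, 0.97;
}
probability ( Hyperlipidemia | PhysicalActivity, Gender, BMI ) {
  ( Insufficient, male, <18.5 ) 0.64851, 0.35149;
  ( Insufficient, male, 18.5~ ) 0.57515, 0.42485;
  ( Insufficient, male, 24.0~ ) 0.37926, 0.62074;
  ( Insufficient, male, 28.0~ ) 0.24727, 0.75273;
  ( Insufficient, female, <18.5 ) 0.69397, 0.30603;
  ( Insufficient, female, 18.5~ ) 0.57664, 0.42336;
  ( Insufficient, female, 24.0~ ) 0.5828, 0.4172;
  ( Insufficient, female, 28.0~ ) 0.37888, 0.62112;
  ( Normal, male, <18.5 ) 0.94811, 0.05189;
  ( Normal, male, 18.5~ ) 0.61095, 0.38905;
  ( Normal, male, 24.0~ ) 0.43688, 0.56312;
  ( Normal, male, 28.0~ ) 0.29294, 0.70706;
  ( Normal, female, <18.5 ) 0.82164, 0.17836;
  ( Normal, female, 18.5~ ) 0.70408, 0.29592;
  ( Normal, female, 24.0~ ) 0.52875, 0.47125;
  ( Normal, female, 28.0~ ) 0.43453, 0.56547;
  ( Sufficient, male, <18.5 ) 0.52358, 0.47642;
  ( Sufficient, male, 18.5~ ) 0.66463, 0.33537;
  ( Sufficient, male, 24.0~ ) 0.43642, 0.56358;
  ( Sufficient, male, 28.0~ ) 0.25059, 0.74941;
  ( Sufficient, female, <18.5 ) 0.62195, 0.37805;
  ( Sufficient, female, 18.5~ ) 0.64173, 0.35827;
  ( Sufficient, female, 24.0~ ) 0.55612, 0.44388;
  ( Sufficient, female, 28.0~ ) 0.48239, 0.51761;
}
probability ( Hypertension | Hyperlipidemia, Smoking, SaltIntake, OilIntake, CentralObesity ) {
  ( no, no, <6g, <25g, no ) 0.95, 0.05;
  ( no, no, <6g, <25g, yes ) 0.35, 0.65;
  ( no, no, <6g, ≥25g, no ) 0.35, 0.65;
  ( no, no, <6g, ≥25g, yes ) 0.05, 0.95;
  ( no, no, ≥6g, <25g, no ) 0.35, 0.65;
  ( no, no, ≥6g, <25g, yes ) 0.05, 0.95;
  ( no, no, ≥6g, ≥25g, no ) 0.05, 0.95;
  ( no, no, ≥6g, ≥25g, yes ) 0.05, 0.95;
  ( no, yes, <6g, <25g, no ) 0.35, 0.65;
  ( no, yes, <6g, <25g, yes ) 0.05, 0.95;
  ( no, yes, <6g, ≥25g, no ) 0.05, 0.95;
  ( no, yes, <6g, ≥25g, yes ) 0.05, 0.95;
  ( no, yes, ≥6g, <25g, no ) 0.05, 0.95;
  ( no, yes, ≥6g, <25g, yes ) 0.05, 0.95;
  ( no, yes, ≥6g, ≥25g, no ) 0.05, 0.95;
  ( no, yes, ≥6g, ≥25g, yes ) 0.05, 0.95;
  ( yes, no, <6g, <25g, no ) 0.35, 0.65;
  ( yes, no, <6g, <25g, yes ) 0.05, 0.95;
  ( yes, no, <6g, ≥25g, no ) 0.05, 0.95;
  ( yes, no, <6g, ≥25g, yes ) 0.05, 0.95;
  ( yes, no, ≥6g, <25g, no ) 0.05, 0.95;
  ( yes, no, ≥6g, <25g, yes ) 0.05, 0.95;
  ( yes, no, ≥6g, ≥25g, no ) 0.05, 0.95;
  ( yes, no, ≥6g, ≥25g, yes ) 0.05, 0.95;
  ( yes, yes, <6g, <25g, no ) 0.05, 0.95;
  ( yes, yes, <6g, <25g, yes ) 0.05, 0.95;
  ( yes, yes, <6g, ≥25g, no ) 0.05, 0.95;
  ( yes, yes, <6g, ≥25g, yes ) 0.05, 0.95;
  ( yes, yes, ≥6g, <25g, no ) 0.05, 0.95;
  ( yes, yes, ≥6g, <25g, yes ) 0.05, 0.95;
  ( yes, yes, ≥6g, ≥25g, no ) 0.05, 0.95;
  ( yes, yes, ≥6g, ≥25g, yes ) 0.05, 0.95;
}
probability ( Diabetes | Hyperlipidemia, CentralObesity ) {
  ( no, no ) 0.95, 0.05;
  ( no, yes ) 0.35, 0.65;
  ( yes, no ) 0.35, 0.65;
  ( yes, yes ) 0.05, 0.95;
}
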