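network car20 {
}
variable BatteryAge {
  type discrete [ 2 ] { ok, bad };
}
variable Alternator {
  type discrete [ 2 ] { ok, bad };
}
variable ChargingSystem {
  type discrete [ 2 ] { ok, bad };
}
variable BatteryState {
  type discrete [ 2 ] { ok, bad };
}
variable BatteryVoltage {
  type discrete [ 2 ] { ok, bad };
}
variable MainFuse {
  type discrete [ 2 ] { ok, bad };
}
variable Distributor {
  type discrete [ 2 ] { ok, bad };
}
variable VoltageAtPlug {
  type discrete [ 2 ] { ok, bad };
}
variable SparkPlugs {
  type discrete [ 2 ] { ok, bad };
}
variable SparkTiming {
  type discrete [ 2 ] { ok, bad };
}
variable SparkQuality {
  type discrete [ 2 ] { ok, bad };
}
variable StarterMotor {
  type discrete [ 2 ] { ok, bad };
}
variable Starter {
  type discrete [ 2 ] { ok, bad };
}
variable CarCranks {
  type discrete [ 2 ] { ok, bad };
}
variable FuelPump {
  type discrete [ 2 ] { ok, bad };
}
variable FuelSystem {
  type discrete [ 2 ] { ok, bad };
}
variable AirFilter {
  type discrete [ 2 ] { ok, bad };
}
variable AirSystem {
  type discrete [ 2 ] { ok, bad };
}
variable CarStarts {
  type discrete [ 2 ] { ok, bad };
}
variable Headlights {
  type discrete [ 2 ] { ok, bad };
}
probability ( BatteryAge ) {
  table 0.8, 0.2;
}
probability ( Alternator ) {
  table 0.8, 0.2;
}
probability ( ChargingSystem | Alternator ) {
  ( ok ) 0.95, 0.05;
  ( bad ) 0.35, 0.65;
}
probability ( BatteryState | BatteryAge, ChargingSystem ) {
  ( ok, ok ) 0.95, 0.05;
  ( ok, bad ) 0.35, 0.65;
  ( bad, ok ) 0.35, 0.65;
  ( bad, bad ) 0.05, 0.95;
}
probability ( BatteryVoltage | BatteryState ) {
  ( ok ) 0.95, 0.05;
  ( bad ) 0.35, 0.65;
}
probability ( MainFuse ) {
  table 0.8, 0.2;
}
probability ( Distributor ) {
  table 0.8, 0.2;
}
probability ( VoltageAtPlug | BatteryVoltage, Distributor, MainFuse ) {
  ( ok, ok, ok ) 0.95, 0.05;
  ( ok, ok, bad ) 0.35, 0.65;
  ( ok, bad, ok ) 0.35, 0.65;
  ( ok, bad, bad ) 0.05, 0.95;
  ( bad, ok, ok ) 0.35, 0.65;
  ( bad, ok, bad ) 0.05, 0.95;
  ( bad, bad, ok ) 0.05, 0.95;
  ( bad, bad, bad ) 0.05, 0.95;
}
probability ( SparkPlugs ) {
  table 0.8, 0.2;
}
probability ( SparkTiming | Distributor ) {
  ( ok ) 0.95, 0.05;
  ( bad ) 0.35, 0.65;
}
probability ( SparkQuality | SparkPlugs, SparkTiming, VoltageAtPlug ) {
  ( ok, ok, ok ) 0.95, 0.05;
  ( ok, ok, bad ) 0.35, 0.65;
  ( ok, bad, ok ) 0.35, 0.65;
  ( ok, bad, bad ) 0.05, 0.95;
  ( bad, ok, ok ) 0.35, 0.65;
  ( bad, ok, bad ) 0.05, 0.95;
  ( bad, bad, ok ) 0.05, 0.95;
  ( bad, bad, bad ) 0.05, 0.95;
}
probability ( StarterMotor ) {
  table 0.8, 0.2;
}
probability ( Starter | BatteryVoltage, StarterMotor ) {
  ( ok, ok ) 0.95, 0.05;
  ( ok, bad ) 0.35, 0.65;
  ( bad, ok ) 0.35, 0.65;
  ( bad, bad ) 0.05, 0.95;
}
probability ( CarCranks | BatteryVoltage, Starter ) {
  ( ok, ok ) 0.95, 0.05;
  ( ok, bad ) 0.35, 0.65;
  ( bad, ok ) 0.35, 0.65;
  ( bad, bad ) 0.05, 0.95;
}
probability ( FuelPump ) {
  table 0.8, 0.2;
}
probability ( FuelSystem | FuelPump ) {
  ( ok ) 0.95, 0.05;
  ( bad ) 0.35, 0.65;
}
probability ( AirFilter ) {
  table 0.8, 0.2;
}
probability ( AirSystem | AirFilter ) {
  ( ok ) 0.95, 0.05;
  ( bad ) 0.35, 0.65;
}
probability ( CarStarts | AirSystem, CarCranks, FuelSystem, SparkQuality ) {
  ( ok, ok, ok, ok ) 0.95, 0.05;
  ( ok, ok, ok, bad ) 0.35, 0.65;
  ( ok, ok, bad, ok ) 0.35, 0.65;
  ( ok, ok, bad, bad ) 0.05, 0.95;
  ( ok, bad, ok, ok ) 0.35, 0.65;
  ( ok, bad, ok, bad ) 0.05, 0.95;
  ( ok, bad, bad, ok ) 0.05, 0.95;
  ( ok, bad, bad, bad ) 0.05, 0.95;
  ( bad, ok, ok, ok ) 0.35, 0.65;
  ( bad, ok, ok, bad ) 0.05, 0.95;
  ( bad, ok, bad, ok ) 0.05, 0.95;
  ( bad, ok, bad, bad ) 0.05, 0.95;
  ( bad, bad, ok, ok ) 0.05, 0.95;
  ( bad, bad, ok, bad ) 0.05, 0.95;
  ( bad, bad, bad, ok ) 0.05, 0.95;
  ( bad, bad, bad, bad ) 0.05, 0.95;
}
probability ( Headlights | BatteryVoltage ) {
  ( ok ) 0.95, 0.05;
  ( bad ) 0.35, 0.65;
}
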