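pattern,freq,sev,int,expected_composite
frequency,0,,,0
frequency,1,,,1
frequency,2,,,1
frequency,3,,,2
frequency,4,,,3
severity,,0,,0
severity,,1,,1
severity,,2,,2
severity,,3,,3
severity,,4,,3
interference,,,0,0
interference,,,1,1
interference,,,2,1
interference,,,3,2
interference,,,4,2
frequency_severity,0,0,,0
frequency_severity,0,1,,0
frequency_severity,0,2,,0
frequency_severity,0,3,,0
frequency_severity,0,4,,0
frequency_severity,1,0,,1
frequency_severity,1,1,,1
frequency_severity,1,2,,1
frequency_severity,1,3,,2
frequency_severity,1,4,,2
frequency_severity,2,0,,1
frequency_severity,2,1,,1
frequency_severity,2,2,,2
frequency_severity,2,3,,2
frequency_severity,2,4,,2
frequency_severity,3,0,,1
frequency_severity,3,1,,1
frequency_severity,3,2,,2
frequency_severity,3,3,,3
frequency_severity,3,4,,3
frequency_severity,4,0,,1
frequency_severity,4,1,,1
frequency_severity,4,2,,2
frequency_severity,4,3,,3
frequency_severity,4,4,,3
frequency_interference,0,,0,0
frequency_interference,0,,1,0
frequency_interference,0,,2,0
frequency_interference,0,,3,0
frequency_interference,0,,4,0
frequency_interference,1,,0,1
frequency_interference,1,,1,1
frequency_interference,1,,2,1
frequency_interference,1,,3,2
frequency_interference,1,,4,2
frequency_interference,2,,0,1
frequency_interference,2,,1,1
frequency_interference,2,,2,1
frequency_interference,2,,3,2
frequency_interference,2,,4,2
frequency_interference,3,,0,1
frequency_interference,3,,1,1
frequency_interference,3,,2,2
frequency_interference,3,,3,3
frequency_interference,3,,4,3
frequency_interference,4,,0,1
frequency_interference,4,,1,1
frequency_interference,4,,2,2
frequency_interference,4,,3,3
frequency_interference,4,,4,3
severity_interference,,0,0,0
severity_interference,,0,1,0
severity_interference,,0,2,0
severity_interference,,0,3,0
severity_interference,,0,4,0
severity_interference,,1,0,1
severity_interference,,1,1,1
severity_interference,,1,2,1
severity_interference,,1,3,2
severity_interference,,1,4,2
severity_interference,,2,0,1
severity_interference,,2,1,1
severity_interference,,2,2,2
severity_interference,,2,3,2
severity_interference,,2,4,3
severity_interference,,3,0,1
severity_interference,,3,1,2
severity_interference,,3,2,2
severity_interference,,3,3,3
severity_interference,,3,4,3
severity_interference,,4,0,2
severity_interference,,4,1,2
severity_interference,,4,2,2
severity_interference,,4,3,3
severity_interference,,4,4,3
frequency_severity_interference,0,0,0,0
frequency_severity_interference,0,0,1,0
frequency_severity_interference,0,0,2,0
frequency_severity_interference,0,0,3,0
frequency_severity_interference,0,0,4,0
frequency_severity_interference,0,1,0,0
frequency_severity_interference,0,1,1,0
frequency_severity_interference,0,1,2,0
frequency_severity_interference,0,1,3,0
frequency_severity_interference,0,1,4,0
frequency_severity_interference,0,2,0,0
frequency_severity_interference,0,2,1,0
frequency_severity_interference,0,2,2,0
frequency_severity_interference,0,2,3,0
frequency_severity_interference,0,2,4,0
frequency_severity_interference,0,3,0,0
frequency_severity_interference,0,3,1,0
frequency_severity_interference,0,3,2,0
frequency_severity_interference,0,3,3,0
frequency_severity_interference,0,3,4,0
frequency_severity_interference,0,4,0,0
frequency_severity_interference,0,4,1,0
frequency_severity_interference,0,4,2,0
frequency_severity_interference,0,4,3,0
frequency_severity_interference,0,4,4,0
frequency_severity_interference,1,0,0,0
frequency_severity_interference,1,0,1,1
frequency_severity_interference,1,0,2,1
frequency_severity_interference,1,0,3,2
frequency_severity_interference,1,0,4,2
frequency_severity_interference,1,1,0,1
frequency_severity_interference,1,1,1,1
frequency_severity_interference,1,1,2,1
frequency_severity_interference,1,1,3,2
frequency_severity_interference,1,1,4,2
frequency_severity_interference,1,2,0,1
frequency_severity_interference,1,2,1,2
frequency_severity_interference,1,2,2,2
frequency_severity_interference,1,2,3,2
frequency_severity_interference,1,2,4,3
frequency_severity_interference,1,3,0,2
frequency_severity_interference,1,3,1,2
frequency_severity_interference,1,3,2,2
frequency_severity_interference,1,3,3,3
frequency_severity_interference,1,3,4,3
frequency_severity_interference,1,4,0,2
frequency_severity_interference,1,4,1,2
frequency_severity_interference,1,4,2,3
frequency_severity_interference,1,4,3,3
frequency_severity_interference,1,4,4,3
frequency_severity_interference,2,0,0,0
frequency_severity_interference,2,0,1,1
frequency_severity_interference,2,0,2,1
frequency_severity_interference,2,0,3,2
frequency_severity_interference,2,0,4,2
frequency_severity_interference,2,1,0,1
frequency_severity_interference,2,1,1,1
frequency_severity_interference,2,1,2,1
frequency_severity_interference,2,1,3,2
frequency_severity_interference,2,1,4,2
frequency_severity_interference,2,2,0,2
frequency_severity_interference,2,2,1,2
frequency_severity_interference,2,2,2,2
frequency_severity_interference,2,2,3,3
frequency_severity_interference,2,2,4,3
frequency_severity_interference,2,3,0,2
frequency_severity_interference,2,3,1,2
frequency_severity_interference,2,3,2,2
frequency_severity_interference,2,3,3,3
frequency_severity_interference,2,3,4,3
frequency_severity_interference,2,4,0,2
frequency_severity_interference,2,4,1,2
frequency_severity_interference,2,4,2,3
frequency_severity_interference,2,4,3,3
frequency_severity_interference,2,4,4,3
frequency_severity_interference,3,0,0,1
frequency_severity_interference,3,0,1,1
frequency_severity_interference,3,0,2,1
frequency_severity_interference,3,0,3,2
frequency_severity_interference,3,0,4,2
frequency_severity_interference,3,1,0,1
frequency_severity_interference,3,1,1,1
frequency_severity_interference,3,1,2,1
frequency_severity_interference,3,1,3,2
frequency_severity_interference,3,1,4,2
frequency_severity_interference,3,2,0,2
frequency_severity_interference,3,2,1,2
frequency_severity_interference,3,2,2,2
frequency_severity_interference,3,2,3,3
frequency_severity_interference,3,2,4,3
frequency_severity_interference,3,3,0,2
frequency_severity_interference,3,3,1,2
frequency_severity_interference,3,3,2,3
frequency_severity_interference,3,3,3,3
frequency_severity_interference,3,3,4,3
frequency_severity_interference,3,4,0,2
frequency_severity_interference,3,4,1,2
frequency_severity_interference,3,4,2,3
frequency_severity_interference,3,4,3,3
frequency_severity_interference,3,4,4,3
frequency_severity_interference,4,0,0,1
frequency_severity_interference,4,0,1,1
frequency_severity_interference,4,0,2,1
frequency_severity_interference,4,0,3,2
frequency_severity_interference,4,0,4,2
frequency_severity_interference,4,1,0,1
frequency_severity_interference,4,1,1,1
frequency_severity_interference,4,1,2,2
frequency_severity_interference,4,1,3,2
frequency_severity_interference,4,1,4,3
frequency_severity_interference,4,2,0,2
frequency_severity_interference,4,2,1,2
frequency_severity_interference,4,2,2,2
frequency_severity_interference,4,2,3,3
frequency_severity_interference,4,2,4,3
frequency_severity_interference,4,3,0,2
frequency_severity_interference,4,3,1,2
frequency_severity_interference,4,3,2,3
frequency_severity_interference,4,3,3,3
frequency_severity_interference,4,3,4,3
frequency_severity_interference,4,4,0,2
frequency_severity_interference,4,4,1,2
frequency_severity_interference,4,4,2,3
frequency_severity_interference,4,4,3,3
frequency_severity_interference,4,4,4,3
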