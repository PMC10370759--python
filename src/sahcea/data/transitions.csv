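# source: fixture — synthetic stand-in generated by sahcea.fixtures; not data from the published study or its supplement
# derived from the base-case state_mortality values
from,to,prob
favorable,favorable,0.8933
favorable,dead,0.1067
unfavorable,unfavorable,0.22219999999999995
unfavorable,dead,0.7778
dead,dead,1.0
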