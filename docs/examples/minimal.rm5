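<?xml version='1.0' encoding='UTF-8'?>
<!-- Minimal valid file: a review with no studies and no analyses.
     Lenient and strict reads both succeed (the STUDIES container exists). -->
<COCHRANE_REVIEW ID="EX-MINIMAL" REVMAN_VERSION="5.3">
  <COVER_SHEET><TITLE>Example: an empty review shell</TITLE></COVER_SHEET>
  <STUDIES_AND_REFERENCES><STUDIES><INCLUDED_STUDIES/></STUDIES></STUDIES_AND_REFERENCES>
  <CHARACTERISTICS_OF_STUDIES><CHARACTERISTICS_OF_INCLUDED_STUDIES/></CHARACTERISTICS_OF_STUDIES>
  <RISK_OF_BIAS/>
  <ANALYSES_AND_DATA/>
</COCHRANE_REVIEW>
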