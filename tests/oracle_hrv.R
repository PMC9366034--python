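# Independent HRV oracle: computes the time-domain and Poincare descriptors
# with base R numerics from a long-format CSV (series_id, rr_ms).
# Usage: Rscript oracle_hrv.R input.csv output.csv
args <- commandArgs(trailingOnly = TRUE)
df <- read.csv(args[1], colClasses = c(series_id = "character"))
rows <- lapply(split(df$rr_ms, df$series_id), function(rr) {
  d <- diff(rr)
  data.frame(
    mean_rr = mean(rr),
    sdnn = sd(rr),
    pnn50 = 100 * mean(abs(d) >= 50),
    sd1 = sqrt(0.5 * var(d)),
    sd2 = sqrt(max(2 * var(rr) - 0.5 * var(d), 0))
  )
})
out <- do.call(rbind, rows)
out$series_id <- names(rows)
write.csv(out, args[2], row.names = FALSE)
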